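"""Multistate transition structure.

A multistate model without loops is a finite set of states together with a
set of allowed direct transitions whose directed graph is acyclic.  A subset
of states may be declared *exactly observed*: entry into such a state is
recorded at its exact time (death is the canonical example), while all other
transitions are only known up to the visit interval in which they occurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

from .exceptions import CycleError, UnknownStateError, UnknownTransitionError

__all__ = [
    "TransitionGraph",
    "validate_graph",
    "illness_death",
    "extended_illness_death",
    "load_model_config",
]


@dataclass(frozen=True)
class TransitionGraph:
    """States, allowed direct transitions and exactly-observed states.

    Parameters
    ----------
    states : tuple
        Ordered state labels.  Internally states are handled as 0-based
        indices in this order; all I/O uses the labels.
    transitions : tuple of (int, int)
        Allowed direct transitions as 0-based index pairs.
    exact_states : frozenset of int
        Indices of states whose entry times are observed exactly.

    Use :func:`validate_graph` (or the convenience constructors) rather than
    instantiating directly: validation establishes acyclicity and builds the
    derived lookup tables.
    """

    states: tuple
    transitions: tuple
    exact_states: frozenset = frozenset()
    # derived, filled in by validate_graph
    topo_order: tuple = field(default=(), compare=False)
    _reach: np.ndarray = field(default=None, compare=False, repr=False)

    # -- basic queries -----------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def index(self, label) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise UnknownStateError(f"unknown state label {label!r}") from None

    def label(self, idx: int):
        return self.states[idx]

    def transition_index(self, g: int, h: int) -> int:
        """Position of (g, h) in ``self.transitions``."""
        try:
            return self.transitions.index((g, h))
        except ValueError:
            raise UnknownTransitionError(
                f"{self.label(g)!r} -> {self.label(h)!r} is not an allowed "
                "direct transition"
            ) from None

    def successors(self, g: int) -> tuple:
        """States directly reachable from g (one transition)."""
        return tuple(h for (a, h) in self.transitions if a == g)

    def reachable_from(self, h: int) -> tuple:
        """R_h: states with a direct edge into h."""
        return tuple(g for (g, b) in self.transitions if b == h)

    def is_absorbing(self, g: int) -> bool:
        return len(self.successors(g)) == 0

    def can_reach(self, g: int, h: int) -> bool:
        """Whether a directed path (possibly empty) leads from g to h."""
        return bool(self._reach[g, h])

    @property
    def transition_mask(self) -> np.ndarray:
        """Boolean (H, H) matrix of allowed direct transitions."""
        mask = np.zeros((self.n_states, self.n_states), dtype=bool)
        for g, h in self.transitions:
            mask[g, h] = True
        return mask

    def transition_labels(self) -> list:
        return [(self.label(g), self.label(h)) for g, h in self.transitions]


def validate_graph(
    states: Sequence[Hashable],
    transitions: Iterable,
    exact_states: Iterable = (),
) -> TransitionGraph:
    """Validate a multistate structure and return a :class:`TransitionGraph`.

    ``transitions`` and ``exact_states`` are given in terms of the state
    labels.  Raises :class:`CycleError` if the directed graph has a cycle or
    self-loop, :class:`UnknownStateError` on undeclared labels.
    """
    states = tuple(states)
    if len(set(states)) != len(states):
        raise UnknownStateError("duplicate state labels")
    idx = {s: i for i, s in enumerate(states)}

    pairs = []
    for g, h in transitions:
        if g not in idx:
            raise UnknownStateError(f"transition references unknown state {g!r}")
        if h not in idx:
            raise UnknownStateError(f"transition references unknown state {h!r}")
        if g == h:
            raise CycleError(f"self-loop on state {g!r} is not allowed")
        pairs.append((idx[g], idx[h]))
    pairs = tuple(dict.fromkeys(pairs))  # dedupe, keep order

    exact = []
    for e in exact_states:
        if e not in idx:
            raise UnknownStateError(f"exact state {e!r} not declared")
        exact.append(idx[e])

    G = nx.DiGraph()
    G.add_nodes_from(range(len(states)))
    G.add_edges_from(pairs)
    try:
        topo = tuple(nx.topological_sort(G))
    except nx.NetworkXUnfeasible:
        raise CycleError("transition structure contains a directed cycle") from None

    H = len(states)
    reach = np.eye(H, dtype=bool)
    for g in range(H):
        for h in nx.descendants(G, g):
            reach[g, h] = True

    return TransitionGraph(
        states=states,
        transitions=pairs,
        exact_states=frozenset(exact),
        topo_order=topo,
        _reach=reach,
    )


def illness_death(exact_death: bool = False) -> TransitionGraph:
    """Standard illness-death model 1->2, 1->3, 2->3."""
    return validate_graph(
        (1, 2, 3), [(1, 2), (1, 3), (2, 3)], exact_states=(3,) if exact_death else ()
    )


def extended_illness_death(exact_death: bool = True) -> TransitionGraph:
    """Extended illness-death model 1->2, 1->3, 2->4.

    States 3 (death without illness) and 4 (death after illness) are kept
    separate; by default both are exactly observed.
    """
    return validate_graph(
        (1, 2, 3, 4), [(1, 2), (1, 3), (2, 4)],
        exact_states=(3, 4) if exact_death else (),
    )


def load_model_config(path) -> TransitionGraph:
    """Read a model config (YAML/JSON) with keys ``states``, ``transitions``
    (list of [from, to] pairs) and optional ``exact_states``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "states" not in cfg or "transitions" not in cfg:
        raise UnknownStateError(
            f"model config {path} must define 'states' and 'transitions'"
        )
    return validate_graph(
        cfg["states"],
        [tuple(p) for p in cfg["transitions"]],
        cfg.get("exact_states") or (),
    )
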