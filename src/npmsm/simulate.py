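"""Synthetic interval-censored multistate panels.

Latent paths are drawn from a Markov multistate process with cause-specific
exponential or Weibull hazards on the study time scale (``clock='forward'``:
in state g at time s, each candidate transition time is drawn from its
distribution conditional on exceeding s, and the minimum wins; this keeps
the generated process Markov, matching the estimator's assumption).  A
``clock='reset'`` semi-Markov option is available for robustness
experiments only.

The Weibull family uses survivor function exp(-lambda t^k) (density
lambda k t^{k-1} exp(-lambda t^k)); shape k = 1 reduces to the
exponential(lambda).

Paths are then observed through a visit process: a renewal scheme with
uniform inter-visit times, or a fixed panel scheme (visits near multiples of
a period with uniform jitter).  Observation stops at an administrative
horizon; entries into exactly-observed states are recorded at their true
times; visits after the first observation in an absorbing state carry no
information and are dropped.

Six preset scenarios cover an (extended) illness-death process over a
15-year study with mean transition times 10 (1->2), 20 (1->3) and 10 years
(2->3 or 2->4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from .graph import TransitionGraph, extended_illness_death, illness_death, validate_graph
from .panel import ObservationPath, PanelDataset

__all__ = [
    "Hazard",
    "VisitScheme",
    "ScenarioSpec",
    "TruePath",
    "sample_path",
    "observe_path",
    "scenario_preset",
    "simulate_dataset",
    "load_scenario",
]


@dataclass(frozen=True)
class Hazard:
    """Cause-specific hazard: 'exponential' (rate) or 'weibull'
    (rate, shape) with cumulative hazard rate * t**shape."""

    family: str
    rate: float
    shape: float = 1.0

    def __post_init__(self):
        if self.family not in ("exponential", "weibull"):
            raise ValueError(f"unknown hazard family {self.family!r}")
        if self.rate <= 0 or self.shape <= 0:
            raise ValueError("hazard parameters must be positive")

    @property
    def k(self) -> float:
        return 1.0 if self.family == "exponential" else self.shape

    def cumulative(self, t):
        """Lambda(t) = rate * t**k."""
        return self.rate * np.asarray(t, dtype=float) ** self.k

    def intensity(self, t):
        """lambda(t) = rate * k * t**(k-1)."""
        t = np.asarray(t, dtype=float)
        return self.rate * self.k * t ** (self.k - 1.0)

    def mean(self) -> float:
        """E[T] = rate**(-1/k) * Gamma(1 + 1/k)."""
        return self.rate ** (-1.0 / self.k) * math.gamma(1.0 + 1.0 / self.k)

    def sample_conditional(self, s: float, rng: np.random.Generator) -> float:
        """Draw T from the distribution conditional on T > s:
        T = (s**k - log(U)/rate)**(1/k)."""
        u = rng.random()
        return (s ** self.k - math.log(u) / self.rate) ** (1.0 / self.k)

    def sample(self, rng: np.random.Generator) -> float:
        return self.sample_conditional(0.0, rng)


@dataclass(frozen=True)
class VisitScheme:
    """Visit process: 'renewal' draws inter-visit gaps U(low, high); 'panel'
    schedules visits at period*j + U(-jitter, jitter)."""

    kind: str
    low: float = 0.0
    high: float = 4.4
    period: float = 3.0
    jitter: float = 0.1

    def visit_times(self, horizon: float, rng: np.random.Generator) -> list:
        times = []
        if self.kind == "renewal":
            t = 0.0
            while True:
                t += rng.uniform(self.low, self.high)
                if t > horizon:
                    break
                times.append(t)
        elif self.kind == "panel":
            j = 1
            while True:
                t = self.period * j + rng.uniform(-self.jitter, self.jitter)
                if t > horizon:
                    break
                times.append(t)
                j += 1
        else:
            raise ValueError(f"unknown visit scheme {self.kind!r}")
        return times


@dataclass(frozen=True)
class ScenarioSpec:
    """Full data-generating design for one simulation scenario."""

    graph: TransitionGraph
    hazards: dict  # label pair -> Hazard
    start_distribution: np.ndarray
    visits: VisitScheme
    horizon: float = 15.0
    clock: str = "forward"

    def __post_init__(self):
        p = np.asarray(self.start_distribution, dtype=float)
        object.__setattr__(self, "start_distribution", p)
        if p.shape != (self.graph.n_states,) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("start distribution must sum to 1 over states")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.clock not in ("forward", "reset"):
            raise ValueError(f"unknown clock {self.clock!r}")
        for pair in self.hazards:
            g, h = pair
            self.graph.transition_index(self.graph.index(g), self.graph.index(h))

    def hazard(self, g_idx: int, h_idx: int) -> Hazard:
        return self.hazards[(self.graph.label(g_idx), self.graph.label(h_idx))]


@dataclass
class TruePath:
    """Latent path: (entry_time, state index) pairs from time 0 onwards."""

    entry_times: np.ndarray
    states: np.ndarray

    def state_at(self, t: float) -> int:
        """State occupied at time t (right-continuous)."""
        j = int(np.searchsorted(self.entry_times, t, side="right")) - 1
        return int(self.states[max(j, 0)])


def sample_path(spec: ScenarioSpec, rng: np.random.Generator) -> TruePath:
    """Draw one latent path from time 0 until absorption or the horizon."""
    g = int(rng.choice(spec.graph.n_states, p=spec.start_distribution))
    times, states = [0.0], [g]
    t = 0.0
    while True:
        exits = spec.graph.successors(g)
        if not exits:
            break
        best_t, best_h = np.inf, -1
        for h in exits:
            hz = spec.hazard(g, h)
            if spec.clock == "forward":
                cand = hz.sample_conditional(t, rng)
            else:
                cand = t + hz.sample(rng)
            if cand < best_t:
                best_t, best_h = cand, h
        if best_t > spec.horizon:
            break
        t, g = best_t, best_h
        times.append(t)
        states.append(g)
    return TruePath(np.array(times), np.array(states, dtype=int))


def observe_path(path: TruePath, spec: ScenarioSpec,
                 rng: np.random.Generator, subject_id=None) -> ObservationPath:
    """Observe a latent path through the visit process.

    The baseline visit is at time 0.  Entries into exactly-observed states
    within the horizon are inserted at their true times.  Visits after the
    first observation in an absorbing state are dropped.
    """
    obs = {0.0: path.state_at(0.0)}
    for t in spec.visits.visit_times(spec.horizon, rng):
        obs[t] = path.state_at(t)
    E = spec.graph.exact_states
    for t, s in zip(path.entry_times[1:], path.states[1:]):
        if int(s) in E and t <= spec.horizon:
            obs[float(t)] = int(s)

    times = sorted(obs)
    states = [obs[t] for t in times]
    trimmed_t, trimmed_s = [], []
    for t, s in zip(times, states):
        trimmed_t.append(t)
        trimmed_s.append(s)
        if spec.graph.is_absorbing(s):
            break
    return ObservationPath(subject_id, np.array(trimmed_t),
                           np.array(trimmed_s, dtype=int))


_EXP_HAZARDS_ID = {
    (1, 2): Hazard("exponential", 0.1),
    (1, 3): Hazard("exponential", 0.05),
    (2, 3): Hazard("exponential", 0.1),
}


def scenario_preset(number: int, variant: str = "dense") -> ScenarioSpec:
    """The six study designs.

    1. illness-death, all start healthy, Exp hazards, visits U[0,4.4]
    2. as 1 but starting state uniform on {healthy, ill}
    3. as 1 but Weibull hazards with the same mean transition times
       (10, 20, 10 years): shapes 0.5/0.5/2, rates 1/sqrt(5), 1/sqrt(10),
       Gamma(1.5)^2/100
    4. extended illness-death with both death states exactly observed
    5. as 2 with panel visits at 3j +- U(0, 0.1)
    6. as 2 with visits U[0,2.44] ('dense') or U[0,7.33] ('sparse')
    """
    if number not in range(1, 7):
        raise ValueError("scenario number must be in 1..6")
    id_graph = illness_death()
    u44 = VisitScheme("renewal", 0.0, 4.4)
    start1 = [1.0, 0.0, 0.0]
    start12 = [0.5, 0.5, 0.0]

    if number == 1:
        return ScenarioSpec(id_graph, dict(_EXP_HAZARDS_ID), start1, u44)
    if number == 2:
        return ScenarioSpec(id_graph, dict(_EXP_HAZARDS_ID), start12, u44)
    if number == 3:
        g15 = math.gamma(1.5)
        hz = {
            (1, 2): Hazard("weibull", 1.0 / math.sqrt(5.0), 0.5),
            (1, 3): Hazard("weibull", 1.0 / math.sqrt(10.0), 0.5),
            (2, 3): Hazard("weibull", g15 ** 2 / 100.0, 2.0),
        }
        return ScenarioSpec(id_graph, hz, start1, u44)
    if number == 4:
        eid = extended_illness_death(exact_death=True)
        hz = {
            (1, 2): Hazard("exponential", 0.1),
            (1, 3): Hazard("exponential", 0.05),
            (2, 4): Hazard("exponential", 0.1),
        }
        return ScenarioSpec(eid, hz, [1.0, 0.0, 0.0, 0.0], u44)
    if number == 5:
        return ScenarioSpec(id_graph, dict(_EXP_HAZARDS_ID), start12,
                            VisitScheme("panel", period=3.0, jitter=0.1))
    # scenario 6
    if variant == "dense":
        scheme = VisitScheme("renewal", 0.0, 2.44)
    elif variant == "sparse":
        scheme = VisitScheme("renewal", 0.0, 7.33)
    else:
        raise ValueError("scenario 6 variant must be 'dense' or 'sparse'")
    return ScenarioSpec(id_graph, dict(_EXP_HAZARDS_ID), start12, scheme)


def simulate_dataset(spec: ScenarioSpec, n: int, seed: int) -> PanelDataset:
    """Simulate a panel of n independent subjects.

    Per-subject RNG substreams are derived from (seed, subject index), so
    enlarging n leaves earlier subjects unchanged.  The latent paths are
    attached as ``dataset.true_paths`` for evaluation.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    paths, truths = [], []
    for i in range(n):
        rng = np.random.default_rng((seed, i))
        truth = sample_path(spec, rng)
        paths.append(observe_path(truth, spec, rng, subject_id=i))
        truths.append(truth)
    ds = PanelDataset(paths, spec.graph)
    ds.true_paths = truths
    return ds


def load_scenario(path) -> ScenarioSpec:
    """Read a scenario spec from YAML/JSON (mirrors ScenarioSpec fields)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    graph = validate_graph(cfg["states"],
                           [tuple(p) for p in cfg["transitions"]],
                           cfg.get("exact_states") or ())
    hazards = {}
    for item in cfg["hazards"]:
        pair = (item["from"], item["to"])
        hazards[pair] = Hazard(item["family"], float(item["rate"]),
                               float(item.get("shape", 1.0)))
    v = cfg["visits"]
    visits = VisitScheme(v["kind"], low=float(v.get("low", 0.0)),
                         high=float(v.get("high", 4.4)),
                         period=float(v.get("period", 3.0)),
                         jitter=float(v.get("jitter", 0.1)))
    return ScenarioSpec(graph, hazards, cfg["start_distribution"], visits,
                        horizon=float(cfg.get("horizon", 15.0)),
                        clock=cfg.get("clock", "forward"))
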