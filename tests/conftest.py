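"""Shared fixtures: tiny hand-built panels and random dataset generators."""

import numpy as np
import pytest

from npmsm import (
    IntensityGrid,
    ObservationPath,
    PanelDataset,
    validate_graph,
)


@pytest.fixture(scope="session")
def two_state_graph():
    return validate_graph((1, 2), [(1, 2)])


@pytest.fixture(scope="session")
def id_graph():
    return validate_graph((1, 2, 3), [(1, 2), (1, 3), (2, 3)])


@pytest.fixture(scope="session")
def id_graph_exact():
    return validate_graph((1, 2, 3), [(1, 2), (1, 3), (2, 3)],
                          exact_states=(3,))


@pytest.fixture(scope="session")
def eid_graph():
    return validate_graph((1, 2, 3, 4), [(1, 2), (1, 3), (2, 4)],
                          exact_states=(3, 4))


@pytest.fixture
def hand_two_state(two_state_graph):
    """One subject seen healthy at 0 and failed by 2, on grid {1, 2}, with
    constant guess alpha = 0.5 per bin (the worked E-step example)."""
    path = ObservationPath("s1", np.array([0.0, 2.0]), np.array([0, 1]))
    ds = PanelDataset([path], two_state_graph, extra_times=[1.0])
    alpha = np.zeros((2, 2, 2))
    alpha[:, 0, 1] = 0.5
    return ds, IntensityGrid(two_state_graph, ds.grid, alpha)


def make_random_twostate(n, seed, graph):
    """Random interval-censored survival panel: all subjects start in the
    initial state at time 0, event times exponential, visit gaps uniform."""
    rng = np.random.default_rng(seed)
    paths = []
    for i in range(n):
        nv = int(rng.integers(1, 6))
        t = np.concatenate(
            [[0.0], np.round(np.cumsum(rng.uniform(0.2, 3.0, nv)), 3)]
        )
        event = rng.exponential(3.0)
        st = (t >= event).astype(int)
        if st.any():
            cut = int(np.argmax(st)) + 1
            t, st = t[:cut], st[:cut]
        if len(t) > 1:
            paths.append(ObservationPath(i, t, st))
    return PanelDataset(paths, graph)


@pytest.fixture(scope="session")
def random_twostate_factory(two_state_graph):
    return lambda n, seed: make_random_twostate(n, seed, two_state_graph)


def make_tiny_instance(seed, graphs):
    """Random tiny multistate panel within the brute-force size cap
    (H <= 3, K <= 3, n <= 4)."""
    rng = np.random.default_rng(seed)
    g = graphs[int(rng.integers(0, len(graphs)))]
    taus = np.sort(rng.choice([1.0, 2.0, 3.0],
                              size=int(rng.integers(2, 4)), replace=False))
    paths = []
    for i in range(int(rng.integers(2, 5))):
        tsel = np.sort(rng.choice(taus, size=int(rng.integers(1, len(taus) + 1)),
                                  replace=False))
        states = [0]
        for _ in tsel:
            nxt = [h for h in range(g.n_states)
                   if g.can_reach(states[-1], h)]
            states.append(int(rng.choice(nxt)))
        paths.append(ObservationPath(
            i, np.concatenate([[0.0], tsel]), np.array(states, dtype=int)))
    return PanelDataset(paths, g, extra_times=taus)


@pytest.fixture(scope="session")
def tiny_instance_factory(two_state_graph, id_graph):
    graphs = (two_state_graph, id_graph)
    return lambda seed: make_tiny_instance(seed, graphs)
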