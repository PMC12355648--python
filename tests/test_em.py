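"""E-step, M-step, likelihood and EM driver."""

import warnings

import numpy as np
import pytest

from npmsm import (
    ExpectedCounts,
    FitConfig,
    IntensityGrid,
    MaxIterWarning,
    ObservationPath,
    PanelDataset,
    ZeroPathError,
    e_step,
    e_step_exact,
    expected_counts,
    fit_em,
    kkt_check,
    m_step,
    observed_loglik,
    reduced_gradient,
    scenario_preset,
    simulate_dataset,
    validate_graph,
)
from npmsm.oracles import naive_loglik


# --- E-step -----------------------------------------------------------------

def test_e_step_hand_example(hand_two_state):
    """Subject seen 1 at t=0 and 2 at t=2 on grid {1,2} with alpha=0.5:
    expected jumps (2/3, 1/3), at-risk (1, 1/3)."""
    ds, ag = hand_two_state
    c = expected_counts(ag, ds)
    assert c.d[:, 0, 1] == pytest.approx([2 / 3, 1 / 3])
    assert c.Y[:, 0] == pytest.approx([1.0, 1 / 3])
    assert c.loglik == pytest.approx(np.log(0.75))


def test_e_step_contributions_bounded(id_graph):
    """Per-subject contributions to d and Y lie in [0, 1]."""
    p = ObservationPath("a", np.array([0.0, 3.0]), np.array([0, 0]))
    ds = PanelDataset([p], id_graph, extra_times=[1.0, 2.0])
    alpha = np.zeros((3, 3, 3))
    for g, h in id_graph.transitions:
        alpha[:, g, h] = 0.2
    c = expected_counts(IntensityGrid(id_graph, ds.grid, alpha), ds)
    assert np.all(c.d >= 0) and np.all(c.d.sum(axis=(1, 2)) <= 1 + 1e-12)
    assert np.all((c.Y >= 0) & (c.Y <= 1 + 1e-12))


def test_e_step_absorbing_frame_contributes_nothing(id_graph):
    p = ObservationPath("a", np.array([0.0, 2.0, 4.0]), np.array([0, 2, 2]))
    ds = PanelDataset([p], id_graph)
    alpha = np.zeros((2, 3, 3))
    for g, h in id_graph.transitions:
        alpha[:, g, h] = 0.3
    c = expected_counts(IntensityGrid(id_graph, ds.grid, alpha), ds)
    # the (2,4] frame has a = b = absorbing: no jumps, no transient risk
    k = ds.grid.index_of(4.0)
    assert c.d[k].sum() == 0.0
    assert c.Y[k, 0] == 0.0 and c.Y[k, 1] == 0.0


def test_exact_e_step_hand_example(id_graph_exact):
    """Illness-death with exact death at tau_2 and alpha=0.5 everywhere:
    the observed death time forces the illness path."""
    p = ObservationPath("a", np.array([0.0, 2.0]), np.array([0, 2]))
    ds = PanelDataset([p], id_graph_exact, extra_times=[1.0])
    alpha = np.zeros((2, 3, 3))
    alpha[:, 0, 1] = alpha[:, 0, 2] = alpha[:, 1, 2] = 0.5
    ag = IntensityGrid(id_graph_exact, ds.grid, alpha)
    c = expected_counts(ag, ds)
    assert c.d[0, 0, 1] == pytest.approx(1.0)   # 1->2 in bin 1
    assert c.d[0, 0, 2] == pytest.approx(0.0)
    assert c.d[1, 1, 2] == pytest.approx(1.0)   # 2->3 at the exact time
    assert c.d[1, 0, 2] == pytest.approx(0.0)
    assert c.loglik == pytest.approx(np.log(0.25))  # D = 0.25
    # at the terminal bin the subject is at risk in the predecessor state
    assert c.Y[1, 1] == pytest.approx(1.0)
    assert c.Y[1, 0] == pytest.approx(0.0)


def test_exact_e_step_direct_route(id_graph_exact):
    """Same subject with alpha_12 = 0: all mass flows through 1->3."""
    p = ObservationPath("a", np.array([0.0, 2.0]), np.array([0, 2]))
    ds = PanelDataset([p], id_graph_exact, extra_times=[1.0])
    alpha = np.zeros((2, 3, 3))
    alpha[:, 0, 2] = alpha[:, 1, 2] = 0.5
    c = expected_counts(IntensityGrid(id_graph_exact, ds.grid, alpha), ds)
    assert c.d[1, 0, 2] == pytest.approx(1.0)
    assert c.d[1, 1, 2] == pytest.approx(0.0)
    assert c.d[0].sum() == pytest.approx(0.0)


def test_e_step_split_matches_total(eid_graph):
    ds = simulate_dataset(scenario_preset(4), 40, 3)
    ag = IntensityGrid.uniform(eid_graph, ds.grid)
    total = expected_counts(ag, ds)
    parts = e_step(ag, ds) + e_step_exact(ag, ds)
    assert np.allclose(parts.d, total.d)
    assert np.allclose(parts.Y, total.Y)
    assert parts.loglik == pytest.approx(total.loglik)


def test_e_step_without_exact_states_is_plain(id_graph):
    ds = simulate_dataset(scenario_preset(1), 30, 5)
    ag = IntensityGrid.uniform(id_graph, ds.grid)
    plain = e_step(ag, ds)
    total = expected_counts(ag, ds)
    assert np.allclose(plain.d, total.d) and np.allclose(plain.Y, total.Y)


def test_zero_path_error_names_subject(two_state_graph):
    p = ObservationPath("bad", np.array([0.0, 1.0]), np.array([0, 1]))
    ds = PanelDataset([p], two_state_graph)
    ag = IntensityGrid.zeros(two_state_graph, ds.grid)  # P_12 = 0
    with pytest.raises(ZeroPathError, match="bad"):
        expected_counts(ag, ds)
    assert observed_loglik(ag, ds) == -np.inf


# --- M-step -----------------------------------------------------------------

def _counts_for(graph, grid, d12, d13, Y):
    H = graph.n_states
    d = np.zeros((grid.K, H, H))
    Yv = np.zeros((grid.K, H))
    d[0, 0, 1], d[0, 0, 2] = d12, d13
    Yv[0, 0] = Y
    return ExpectedCounts(d, Yv, 0.0)


def test_m_step_interior_branch(id_graph):
    from npmsm import TimeGrid

    grid = TimeGrid([1.0])
    c = _counts_for(id_graph, grid, 0.25, 0.35, 2.0)
    out = m_step(c, id_graph, grid)
    assert out.alpha[0, 0, 1] == pytest.approx(0.125)
    assert out.alpha[0, 0, 2] == pytest.approx(0.175)


def test_m_step_boundary_branch(id_graph):
    from npmsm import TimeGrid

    grid = TimeGrid([1.0])
    c = _counts_for(id_graph, grid, 0.5, 0.7, 1.0)  # mu = 0.2 > 0
    out = m_step(c, id_graph, grid)
    assert out.alpha[0, 0, 1] == pytest.approx(5 / 12)
    assert out.alpha[0, 0, 2] == pytest.approx(7 / 12)
    assert out.alpha[0, 0].sum() == pytest.approx(1.0)


def test_m_step_empty_risk_set(id_graph):
    from npmsm import TimeGrid

    grid = TimeGrid([1.0])
    c = _counts_for(id_graph, grid, 0.0, 0.0, 0.0)
    out = m_step(c, id_graph, grid)
    assert np.all(out.alpha == 0.0)


def test_m_step_stays_in_constraint_region(id_graph):
    """Random nonnegative counts always map into C_alpha (validated on
    construction, which raises otherwise)."""
    from npmsm import TimeGrid

    rng = np.random.default_rng(1)
    grid = TimeGrid([1.0, 2.0, 3.0])
    for _ in range(50):
        d = np.zeros((3, 3, 3))
        for g, h in id_graph.transitions:
            d[:, g, h] = rng.exponential(1.0, size=3)
        Y = rng.exponential(1.0, size=(3, 3))
        out = m_step(ExpectedCounts(d, Y, 0.0), id_graph, grid)
        assert np.all(out.alpha.sum(axis=2) <= 1 + 1e-12)


# --- observed likelihood ----------------------------------------------------

def test_loglik_trivial_and_hand_value(two_state_graph):
    p = ObservationPath("a", np.array([0.0, 1.0, 3.0]), np.array([0, 0, 0]))
    ds = PanelDataset([p], two_state_graph)
    assert observed_loglik(IntensityGrid.zeros(two_state_graph, ds.grid),
                           ds) == pytest.approx(0.0)


def test_loglik_two_state_example(hand_two_state):
    ds, ag = hand_two_state
    assert observed_loglik(ag, ds) == pytest.approx(np.log(0.75))


@pytest.mark.parametrize("scenario,n,seed", [(1, 25, 0), (2, 25, 1),
                                             (4, 25, 2)])
def test_loglik_matches_naive_product(scenario, n, seed):
    """Dual route: forward/backward accumulation in the E-step kernel equals
    plain ordered matrix products (including exact-state terms)."""
    ds = simulate_dataset(scenario_preset(scenario), n, seed)
    ag = IntensityGrid.uniform(ds.graph, ds.grid)
    assert observed_loglik(ag, ds) == pytest.approx(
        naive_loglik(ag.alpha, ds), abs=1e-10)


# --- EM driver --------------------------------------------------------------

def test_fixed_point_two_state(hand_two_state):
    ds, ag = hand_two_state
    res = fit_em(ds, FitConfig(tol=1e-12, init=ag))
    assert res.alpha_hat.alpha[:, 0, 1] == pytest.approx([2 / 3, 1.0])
    assert res.alpha_hat.product_integral(0, 2)[0, 1] == pytest.approx(1.0)
    assert res.n_iter <= 3 and res.converged


def test_all_staying_subjects_give_zero(two_state_graph):
    paths = [ObservationPath(i, np.array([0.0, 1.0 + i, 4.0 + i]),
                             np.zeros(3, dtype=int)) for i in range(3)]
    ds = PanelDataset(paths, two_state_graph)
    res = fit_em(ds, FitConfig(tol=1e-8))
    assert np.all(res.alpha_hat.alpha == 0.0)
    assert res.loglik == pytest.approx(0.0)


@pytest.mark.parametrize("scenario,seed", [(1, 10), (2, 11), (3, 12),
                                           (4, 13), (5, 14)])
def test_loglik_trace_nondecreasing(scenario, seed):
    ds = simulate_dataset(scenario_preset(scenario), 30, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MaxIterWarning)
        res = fit_em(ds, FitConfig(tol=1e-6, max_iter=3000))
    assert np.all(np.diff(res.trace_loglik) >= -1e-9)
    assert res.loglik >= res.trace_loglik[0]


def test_zero_stays_zero(hand_two_state):
    """A jump that is exactly zero at some iteration stays zero."""
    ds, _ = hand_two_state
    g = ds.graph
    alpha = np.zeros((2, 2, 2))
    alpha[0, 0, 1] = 0.9  # second bin zero
    with pytest.warns(UserWarning, match="zeros"):
        res = fit_em(ds, FitConfig(tol=1e-10,
                                   init=IntensityGrid(g, ds.grid, alpha)))
    assert res.alpha_hat.alpha[1, 0, 1] == 0.0
    assert res.alpha_hat.alpha[0, 0, 1] == pytest.approx(1.0)


def test_reduced_gradient_zero_at_fixed_point(hand_two_state):
    ds, ag = hand_two_state
    res = fit_em(ds, FitConfig(tol=1e-12, init=ag))
    c = expected_counts(res.alpha_hat, ds)
    grad = reduced_gradient(res.alpha_hat, c)
    assert np.max(np.abs(grad[:, ds.graph.transition_mask])) < 1e-9
    assert kkt_check(res.alpha_hat, c, kkt_eps=1e-6)


def test_reduced_gradient_positive_away_from_optimum(id_graph):
    ds = simulate_dataset(scenario_preset(1), 30, 2)
    ag = IntensityGrid.uniform(id_graph, ds.grid)
    c = expected_counts(ag, ds)
    assert reduced_gradient(ag, c).max() > 0
    assert not kkt_check(ag, c, kkt_eps=1e-4)


def test_zero_coordinates_do_not_block_kkt(two_state_graph):
    p = ObservationPath("a", np.array([0.0, 1.0, 3.0]), np.array([0, 0, 0]))
    ds = PanelDataset([p], two_state_graph)
    ag = IntensityGrid.zeros(two_state_graph, ds.grid)
    c = expected_counts(ag, ds)
    assert kkt_check(ag, c, kkt_eps=1e-8)


def test_kkt_criterion_stops(id_graph):
    ds = simulate_dataset(scenario_preset(1), 20, 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MaxIterWarning)
        res = fit_em(ds, FitConfig(criterion="kkt", kkt_eps=1e-3,
                                   max_iter=20000))
    assert res.stop_reason == "kkt"
    assert res.trace_max_grad[-1] < 1e-3


def test_max_iter_warning(id_graph):
    ds = simulate_dataset(scenario_preset(1), 30, 6)
    with pytest.warns(MaxIterWarning):
        res = fit_em(ds, FitConfig(tol=1e-12, max_iter=5))
    assert res.n_iter == 5 and not res.converged


def test_likelihood_criterion(id_graph):
    ds = simulate_dataset(scenario_preset(1), 30, 8)
    res = fit_em(ds, FitConfig(tol=1e-7, criterion="likelihood",
                               max_iter=5000))
    assert res.stop_reason == "likelihood"
    assert abs(np.diff(res.trace_loglik)[-1]) < 1e-7
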