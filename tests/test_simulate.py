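"""Path sampling, observation schemes and scenario presets."""

import math

import numpy as np
import pytest
from scipy import stats

from npmsm import (
    Hazard,
    PanelDataset,
    VisitScheme,
    sample_path,
    scenario_preset,
    simulate_dataset,
)


def test_preset_parameters():
    s1 = scenario_preset(1)
    assert np.allclose(s1.start_distribution, [1, 0, 0])
    assert s1.visits.kind == "renewal" and s1.visits.high == 4.4
    assert s1.horizon == 15.0
    s2 = scenario_preset(2)
    assert np.allclose(s2.start_distribution, [0.5, 0.5, 0])
    s4 = scenario_preset(4)
    assert sorted(s4.graph.label(e) for e in s4.graph.exact_states) == [3, 4]
    s6s = scenario_preset(6, variant="sparse")
    s6d = scenario_preset(6, variant="dense")
    assert (s6s.visits.high, s6d.visits.high) == (7.33, 2.44)


def test_preset3_mean_transition_times():
    """Weibull hazards are calibrated to the exponential means 10, 20, 10."""
    s3 = scenario_preset(3)
    means = {pair: hz.mean() for pair, hz in s3.hazards.items()}
    assert means[(1, 2)] == pytest.approx(10.0)
    assert means[(1, 3)] == pytest.approx(20.0)
    assert means[(2, 3)] == pytest.approx(10.0)
    shapes = [s3.hazards[p].shape for p in [(1, 2), (1, 3), (2, 3)]]
    assert shapes == [0.5, 0.5, 2.0]


def test_weibull_shape_one_is_exponential():
    hz = Hazard("weibull", rate=0.3, shape=1.0)
    rng = np.random.default_rng(0)
    draws = np.array([hz.sample(rng) for _ in range(10_000)])
    assert stats.kstest(draws, "expon", args=(0, 1 / 0.3)).pvalue > 0.01


def test_competing_exponential_exit_rate():
    """Fraction of paths out of the healthy state by t matches the
    closed-form 1 - exp(-0.15 t) of competing exponentials."""
    spec = scenario_preset(1)
    n = 20_000
    left_by_5 = 0
    for i in range(n):
        rng = np.random.default_rng((123, i))
        p = sample_path(spec, rng)
        if len(p.entry_times) > 1 and p.entry_times[1] <= 5.0:
            left_by_5 += 1
    truth = 1 - math.exp(-0.15 * 5.0)
    sd = math.sqrt(truth * (1 - truth) / n)
    assert abs(left_by_5 / n - truth) < 3 * sd


def test_zero_like_hazard_stays_forever():
    spec = scenario_preset(1)
    tiny = {pair: Hazard("exponential", 1e-12)
            for pair in spec.hazards}
    from npmsm import ScenarioSpec

    spec0 = ScenarioSpec(spec.graph, tiny, spec.start_distribution,
                         spec.visits)
    p = sample_path(spec0, np.random.default_rng(0))
    assert len(p.entry_times) == 1


def test_panel_scheme_visit_times():
    scheme = VisitScheme("panel", period=3.0, jitter=0.1)
    rng = np.random.default_rng(5)
    for _ in range(50):
        times = scheme.visit_times(15.0, rng)
        for j, t in enumerate(times, start=1):
            assert abs(t - 3.0 * j) <= 0.1


def test_renewal_visit_count():
    """Average visits over 15 years with U[0,4.4] gaps is near 15/2.2."""
    scheme = VisitScheme("renewal", 0.0, 4.4)
    rng = np.random.default_rng(9)
    counts = [len(scheme.visit_times(15.0, rng)) for _ in range(10_000)]
    assert np.mean(counts) == pytest.approx(15 / 2.2, rel=0.10)


def test_simulate_dataset_determinism_and_substreams():
    spec = scenario_preset(2)
    d1 = simulate_dataset(spec, 15, 42)
    d2 = simulate_dataset(spec, 15, 42)
    assert d1.to_frame().equals(d2.to_frame())
    d3 = simulate_dataset(spec, 30, 42)
    # enlarging n leaves earlier subjects untouched
    f15 = d3.to_frame().query("subject_id < 15").reset_index(drop=True)
    assert f15.equals(d1.to_frame())


def test_all_subjects_start_at_zero_and_censoring():
    ds = simulate_dataset(scenario_preset(1), 300, 7)
    for p in ds.paths:
        assert p.times[0] == 0.0 and p.states[0] == 0
        assert p.times[-1] <= 15.0
    assert isinstance(ds, PanelDataset)  # passed validation on construction


def test_exact_death_times_match_truth():
    """Scenario 4: every observed death time equals the latent entry time."""
    spec = scenario_preset(4)
    ds = simulate_dataset(spec, 200, 11)
    E = spec.graph.exact_states
    for p, truth in zip(ds.paths, ds.true_paths):
        for t, s in zip(p.times, p.states):
            if int(s) in E:
                j = int(np.nonzero(truth.states == s)[0][0])
                assert truth.entry_times[j] == pytest.approx(t)


def test_absorbed_path_yields_two_observations():
    """A path absorbed before the first post-baseline visit gives exactly
    (0, start) and (t1, absorbing) without exact states."""
    spec = scenario_preset(1)
    found = False
    for i in range(500):
        rng = np.random.default_rng((77, i))
        from npmsm import observe_path

        path = sample_path(spec, rng)
        obs = observe_path(path, spec, rng, subject_id=i)
        if len(path.entry_times) > 1 and len(obs) >= 2:
            first_absorbing = obs.states[-1] == 2
            if first_absorbing and len(obs) == 2 and obs.states[0] == 0:
                found = True
                assert obs.times[0] == 0.0
                break
    assert found
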