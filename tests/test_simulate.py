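"""Synthetic dumbbell generator: exactness of the OU discretization,
ground-truth bookkeeping, dwell statistics, and fixture determinism."""

import filecmp

import numpy as np
import pytest
from scipy import stats

import trapstroke as ts
from trapstroke import physics
from trapstroke.simulate import stiffness_matrix


def test_invalid_configs_rejected():
    for kwargs in (
        dict(sample_rate=-1.0),
        dict(detach_rate=-2.0),
        dict(unbound_common_sd=float("nan")),
        dict(slow_population_fraction=1.5),
        dict(mode="quantum"),
    ):
        with pytest.raises(ts.ConfigurationError):
            ts.SimulationConfig(duration=1.0, **kwargs)


def test_no_attachments_gives_stationary_ou_common_mode():
    config = ts.SimulationConfig(duration=40.0, attach_rate=0.0, seed=3)
    trace, truth = ts.simulate_dumbbell(config)
    assert truth == []
    c = 0.5 * (trace.bead_a + trace.bead_b)
    # Stationary variance of the exactly discretized OU process; the
    # effective sample count is duration / (2 tau).
    n_eff = config.duration / (2 * config.common_mode_relax_time)
    rel_tol = 4.0 / np.sqrt(n_eff)
    assert c.var() == pytest.approx(config.unbound_common_sd**2, rel=rel_tol)
    # Autocovariance follows the closed form sigma^2 exp(-dt/tau) at small lags.
    lag = 2
    autocov = np.mean((c[:-lag] - c.mean()) * (c[lag:] - c.mean()))
    expected = config.unbound_common_sd**2 * np.exp(
        -lag / (config.sample_rate * config.common_mode_relax_time)
    )
    assert autocov == pytest.approx(expected, rel=rel_tol)


def test_ground_truth_shifts_match_config():
    config = ts.SimulationConfig(duration=30.0, substep1=3.3, substep2=1.1, seed=5)
    _, truth = ts.simulate_dumbbell(config)
    assert len(truth) > 5
    for ev in truth:
        assert ev.applied_shift_1 == 3.3
        assert ev.applied_shift_2 == 1.1
        assert ev.applied_shift_1 + ev.applied_shift_2 == pytest.approx(4.4)
        assert ev.attach_time < ev.substep2_time < ev.detach_time


def test_single_step_mode_has_no_substep2():
    config = ts.preset_config("r712l", seed=2, duration=30.0)
    assert config.single_step
    _, truth = ts.simulate_dumbbell(config)
    assert len(truth) > 5
    assert all(ev.substep2_time is None for ev in truth)


def test_simulation_deterministic_given_seed():
    config = ts.SimulationConfig(duration=5.0, seed=11)
    trace1, truth1 = ts.simulate_dumbbell(config)
    trace2, truth2 = ts.simulate_dumbbell(ts.SimulationConfig(duration=5.0, seed=11))
    np.testing.assert_array_equal(trace1.bead_a, trace2.bead_a)
    np.testing.assert_array_equal(trace1.bead_b, trace2.bead_b)
    assert truth1 == truth2


def test_dwell_times_pass_ks_against_generating_exponential():
    k = 7.5
    draws = ts.sample_durations([k], [1.0], n=10_000, dead_time=0.0, seed=9)
    assert stats.kstest(draws, "expon", args=(0, 1 / k)).pvalue > 0.01


def test_truncated_mixture_sampler_statistics():
    # All draws exceed the dead time for the saturating-ATP-like mixture.
    d = ts.sample_durations([54.4, 7.5], [0.97, 0.03], n=2000, dead_time=0.015, seed=1)
    assert d.min() >= 0.015
    # Memorylessness: mean of a truncated single exponential is dead_time + 1/k.
    d10 = ts.sample_durations([10.0], [1.0], n=10_000, dead_time=0.1, seed=2)
    assert d10.mean() == pytest.approx(0.2, rel=0.04)
    # Untruncated mean converges to 1/k.
    d0 = ts.sample_durations([25.0], [1.0], n=10_000, dead_time=0.0, seed=3)
    assert d0.mean() == pytest.approx(1 / 25.0, rel=0.04)


def test_duration_sampler_input_validation():
    with pytest.raises(ts.ConfigurationError):
        ts.sample_durations([], [], n=10)
    with pytest.raises(ts.ConfigurationError):
        ts.sample_durations([1.0, 2.0], [0.6, 0.5], n=10)
    with pytest.raises(ts.ConfigurationError):
        ts.sample_durations([1.0], [1.0], n=0)


def test_covariance_contrast_bound_below_unbound():
    config = ts.SimulationConfig(duration=60.0, seed=13)
    trace, truth = ts.simulate_dumbbell(config)
    cov = ts.compute_covariance(trace, 0.030)
    bound = np.zeros(trace.n_samples, dtype=bool)
    for ev in truth:
        i0 = int(ev.attach_time * trace.sample_rate)
        i1 = int(ev.detach_time * trace.sample_rate)
        bound[i0:i1] = True
    assert cov.values[bound].mean() < cov.values[~bound].mean()


def test_mechanistic_equipartition():
    config = ts.SimulationConfig(
        duration=50.0, seed=17, mode="mechanistic", attach_rate=0.0,
        myosin_stiffness=1.0,
    )
    trace, _ = ts.simulate_dumbbell(config)
    assert trace.n_samples >= 1_000_000
    k_inv = np.linalg.inv(stiffness_matrix(config, bound=False))
    expected = config.kbt * k_inv[0, 0]
    assert trace.bead_a.var() == pytest.approx(expected, rel=0.05)
    assert trace.bead_b.var() == pytest.approx(expected, rel=0.05)


def test_mechanistic_stiff_myosin_transmits_full_step():
    # With kappa_m >> kappa_trap the series-spring attenuation
    # kappa_m/(kappa_m + 2 kappa_trap) cancels the calibrated anchor shift,
    # so the mean bound displacement equals the nominal step.
    config = ts.SimulationConfig(
        duration=40.0, seed=19, mode="mechanistic",
        myosin_stiffness=100 * 0.06, substep1=4.0, substep2=0.0,
        substep2_rate=1.0, attach_rate=0.2, detach_rate=0.25,
    )
    trace, truth = ts.simulate_dumbbell(config)
    long_events = [ev for ev in truth if ev.duration > 1.0]
    assert long_events, "need at least one long bound interval"
    disp = 0.5 * (trace.bead_a + trace.bead_b)
    means = []
    for ev in long_events:
        i0 = int(ev.attach_time * config.sample_rate) + 200  # skip relaxation
        i1 = int(ev.detach_time * config.sample_rate)
        means.append(disp[i0:i1].mean())
    attenuation = config.myosin_stiffness / (config.myosin_stiffness + 2 * config.trap_stiffness)
    anchor = 4.0 * (1 + 2 * config.trap_stiffness / config.myosin_stiffness)
    assert anchor * attenuation == pytest.approx(4.0)
    assert np.mean(means) == pytest.approx(4.0, rel=0.02)


def test_fixture_suite_deterministic_and_parameterized(tmp_path):
    m1 = ts.make_fixture_suite(tmp_path / "a", seed=4, trace_duration=4.0)
    ts.make_fixture_suite(tmp_path / "b", seed=4, trace_duration=4.0)
    for name in ("wt_trace.tsv", "r712l_truth.csv", "manifest.json"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)
    wt = m1["fixtures"]["wt"]["parameters"]
    assert wt["substep1"] == 3.32
    assert wt["substep2"] == 1.09
    assert wt["substep2_rate"] == 99.1
    assert wt["detach_rate"] == 4.59
    r712l_truth = ts.simulate.read_ground_truth_csv(tmp_path / "a" / "r712l_truth.csv")
    assert all(ev.substep2_time is None for ev in r712l_truth)


def test_stokes_drag_and_relaxation_time_scale():
    gamma = physics.stokes_drag(250.0)
    # 6*pi*eta*r for a 0.5 um bead in water is a few 1e-6 pN s/nm.
    assert gamma == pytest.approx(4.72e-6, rel=0.01)
    tau = physics.ou_relaxation_time(0.06)
    assert tau == pytest.approx(gamma / 0.06)


def test_two_population_detachment_mixture():
    # With a slow subpopulation the ground-truth dwell mean moves toward the
    # mixture expectation A/k_fast + (1-A)/k_slow.
    config = ts.SimulationConfig(
        duration=400.0, seed=29, substep2=0.0, substep2_rate=1.0,
        detach_rate=20.0, slow_population_fraction=0.25, slow_detach_rate=1.0,
        attach_rate=2.0,
    )
    _, truth = ts.simulate_dumbbell(config)
    durations = np.array([ev.duration for ev in truth])
    assert durations.size > 300
    expected = 0.75 / 20.0 + 0.25 / 1.0
    assert durations.mean() == pytest.approx(expected, rel=0.15)
    # Both populations are represented.
    assert (durations < 0.1).mean() > 0.5
    assert (durations > 0.5).mean() > 0.05
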