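"""Dead-time-truncated exponential-mixture MLE: closed-form oracles,
parameter recovery, model selection, bootstrap, and duty-ratio arithmetic."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import trapstroke as ts
from trapstroke.lifetimes import loglik_truncated_mixture


def test_untruncated_single_exponential_loglik_closed_form():
    rng = np.random.default_rng(0)
    t = rng.exponential(0.2, size=500)
    k = 6.0
    expected = np.sum(np.log(k) - k * t)
    assert loglik_truncated_mixture(t, [k], [1.0], 0.0) == pytest.approx(expected)


def test_numerical_mle_matches_closed_form_truncated_estimator():
    # Oracle: for a dead-time-truncated single exponential the MLE is
    # k = 1/(mean - dead_time); an independent 1-D numerical maximization
    # of the truncated likelihood must agree to 1e-6 relative.
    rng = np.random.default_rng(1)
    dead = 0.015
    t = dead + rng.exponential(1 / 8.0, size=3000)
    closed = 1.0 / (t.mean() - dead)
    numeric = minimize_scalar(
        lambda logk: -loglik_truncated_mixture(t, [np.exp(logk)], [1.0], dead),
        bounds=(np.log(0.1), np.log(500.0)), method="bounded",
        options={"xatol": 1e-12},
    )
    assert np.exp(numeric.x) == pytest.approx(closed, rel=1e-6)
    fit = ts.fit_lifetimes(t, dead_time=dead)[1]
    assert fit.k1 == pytest.approx(closed, rel=1e-6)


def test_mixture_loglik_continuous_in_amplitude_limit():
    rng = np.random.default_rng(2)
    t = rng.exponential(0.1, size=200)
    single = loglik_truncated_mixture(t, [10.0], [1.0], 0.0)
    nearly_single = loglik_truncated_mixture(t, [10.0, 1.0], [1 - 1e-9, 1e-9], 0.0)
    assert nearly_single == pytest.approx(single, abs=1e-4)


def test_loglik_invariant_under_permutation_and_component_swap():
    rng = np.random.default_rng(3)
    t = 0.01 + rng.exponential(0.05, size=100)
    ll = loglik_truncated_mixture(t, [30.0, 5.0], [0.8, 0.2], 0.01)
    shuffled = t.copy()
    rng.shuffle(shuffled)
    assert loglik_truncated_mixture(shuffled, [30.0, 5.0], [0.8, 0.2], 0.01) == pytest.approx(ll)
    assert loglik_truncated_mixture(t, [5.0, 30.0], [0.2, 0.8], 0.01) == pytest.approx(ll)


def test_durations_below_dead_time_rejected():
    with pytest.raises(ts.AnalysisError):
        loglik_truncated_mixture([0.01, 0.2], [5.0], [1.0], dead_time=0.015)
    with pytest.raises(ts.AnalysisError):
        ts.fit_lifetimes(np.array([0.01] * 20), dead_time=0.015)


def test_degenerate_identical_durations_flagged():
    with pytest.raises(ts.AnalysisError):
        ts.fit_lifetimes(np.full(50, 0.1))


def test_single_rate_recovery_with_truncation():
    draws = ts.sample_durations([6.9], [1.0], n=5000, dead_time=0.015, seed=4)
    fit = ts.fit_lifetimes(draws, dead_time=0.015)[1]
    assert fit.k1 == pytest.approx(6.9, rel=3.5 / np.sqrt(5000))


def test_mixture_recovery_dominant_amplitude_convention():
    draws = ts.sample_durations([54.4, 7.5], [0.97, 0.03], n=5000,
                                dead_time=0.015, seed=5)
    fits = ts.fit_lifetimes(draws, dead_time=0.015, seed=5)
    fit2 = fits[2]
    assert fit2.amplitude_a > 0.5          # dominant component listed first
    assert fit2.k1 == pytest.approx(54.4, rel=0.10)
    assert fit2.k2 == pytest.approx(7.5, rel=0.60)
    assert fit2.amplitude_a == pytest.approx(0.97, abs=0.02)
    chosen, p = ts.select_model(fits[1], fits[2])
    assert chosen.model_order == 2
    assert p < 0.05


def test_select_model_zero_statistic_keeps_single_exponential():
    fit1 = ts.LifetimeFit(1, 5.0, None, None, log_likelihood=-100.0,
                          n_durations=50, dead_time=0.0)
    fit2 = ts.LifetimeFit(2, 5.0, 1.0, 0.9, log_likelihood=-100.0,
                          n_durations=50, dead_time=0.0)
    chosen, p = ts.select_model(fit1, fit2)
    assert p == pytest.approx(1.0)
    assert chosen.model_order == 1


def test_bias_small_across_rate_decades():
    # Mean of 8 replicate MLEs at n = 2000 stays within 5% of truth for
    # rates spanning 1-200 /s against a 15 ms dead time.
    dead = 0.015
    for k in (1.0, 10.0, 54.4, 200.0):
        estimates = []
        for rep in range(8):
            draws = ts.sample_durations([k], [1.0], n=2000, dead_time=dead,
                                        seed=1000 + int(k * 10) + rep)
            estimates.append(ts.fit_lifetimes(draws, dead_time=dead)[1].k1)
        assert np.mean(estimates) == pytest.approx(k, rel=0.05)


def test_bootstrap_ci_brackets_point_estimate_and_shrinks():
    dead = 0.015
    widths = []
    for n in (500, 2000):
        draws = ts.sample_durations([12.0], [1.0], n=n, dead_time=dead, seed=6)
        fit = ts.fit_lifetimes(draws, dead_time=dead)[1]
        ci = ts.bootstrap_ci(draws, dead, fit, n_boot=300, seed=7)
        lo, hi = ci["k1"]
        assert lo < fit.k1 < hi
        widths.append(hi - lo)
    # Quadrupling n should roughly halve the CI width.
    assert widths[1] == pytest.approx(widths[0] / 2, rel=0.5)


def test_bootstrap_deterministic_given_seed():
    draws = ts.sample_durations([12.0], [1.0], n=400, dead_time=0.0, seed=8)
    fit = ts.fit_lifetimes(draws)[1]
    ci1 = ts.bootstrap_ci(draws, 0.0, fit, n_boot=200, seed=9)
    ci2 = ts.bootstrap_ci(draws, 0.0, fit, n_boot=200, seed=9)
    assert ci1 == ci2


def test_molecule_inclusion_boundary():
    events = {f"m{n}": list(range(n)) for n in (0, 75, 76, 200)}
    kept = ts.filter_molecules(events)
    assert set(kept) == {"m76", "m200"}
    assert ts.filter_molecules({}) == {}


def test_duty_ratio_values_and_warning():
    assert ts.duty_ratio(54.4, 5.1).value == pytest.approx(0.094, abs=0.001)
    assert ts.duty_ratio(69.7, 5.7).value == pytest.approx(0.082, abs=0.001)
    with pytest.warns(RuntimeWarning):
        assert ts.duty_ratio(5.0, 5.0).value == pytest.approx(1.0)
    with pytest.raises(ts.ConfigurationError):
        ts.duty_ratio(-1.0, 5.0)
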