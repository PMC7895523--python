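"""Ensemble averaging, extension rules, step/substep arithmetic, and rise
fits, checked on constructed noiseless inputs with hand-computed answers."""

import numpy as np
import pytest

import trapstroke as ts
from trapstroke.ensembles import EnsembleAverage, _plateau

FS = 10_000.0
DT = 1.0 / FS
TD = 0.015


def make_trace(disp, molecule_id="m"):
    return ts.TrapTrace(sample_interval=DT, bead_a=disp.copy(), bead_b=disp.copy(),
                        molecule_id=molecule_id)


def plateau_event(t_start, t_end, level, n_total, baseline=0.0):
    """A noiseless displacement trace with one rectangular event, plus the
    Event whose refined bounds frame it the way refinement would."""
    disp = np.full(n_total, baseline)
    i0, i1 = int(t_start * FS), int(t_end * FS)
    disp[i0:i1] = level
    event = ts.Event(raw_start=t_start + 0.015, raw_end=t_end + 0.015,
                     refined_start=t_start - 0.75 * TD, refined_end=t_end + 1.35 * TD)
    return disp, event


def test_event_displacement_identical_beads_and_sign():
    disp, event = plateau_event(1.0, 1.5, 4.4, 30_000)
    trace = make_trace(disp)
    t, y, truncated = ts.event_displacement(trace, event, pad=0.1)
    assert not truncated
    np.testing.assert_array_equal(y, trace.bead_a[int(t[0] * FS):int(t[0] * FS) + y.size])
    assert y.max() == pytest.approx(4.4)
    _, y_neg, _ = ts.event_displacement(trace, event, pad=0.1, sign=-1.0)
    np.testing.assert_allclose(y_neg, -y)


def test_event_displacement_pad_truncation_flagged():
    disp, event = plateau_event(0.05, 0.3, 2.0, 5_000)
    _, _, truncated = ts.event_displacement(make_trace(disp), event, pad=0.2)
    assert truncated


def test_forward_average_of_two_plateaus_is_their_mean():
    n = 40_000
    disp1, ev1 = plateau_event(1.0, 1.4, 1.0, n)
    disp2, ev2 = plateau_event(2.4, 2.7, 3.0, n)
    trace = make_trace(disp1 + disp2)
    fwd = ts.forward_average(trace, [ev1, ev2], extension_span=0.5, pad=0.1, dead_time=TD)
    assert _plateau(fwd) == pytest.approx(2.0, abs=1e-9)
    single = ts.forward_average(trace, [ev1], extension_span=0.5, pad=0.1, dead_time=TD)
    assert _plateau(single) == pytest.approx(1.0, abs=1e-9)


def test_combine_molecules_weights_molecules_equally():
    tau = np.arange(100) * DT
    small = EnsembleAverage("forward", tau, np.full(100, 2.0), n_events=10,
                            n_molecules=1, extension_span=0.5)
    big = EnsembleAverage("forward", tau, np.full(100, 4.0), n_events=1000,
                          n_molecules=1, extension_span=0.5)
    combined = ts.combine_molecules([small, big])
    np.testing.assert_allclose(combined.mean_displacement, 3.0)   # not 3.98
    assert combined.n_events == 1010
    assert combined.n_molecules == 2
    flipped = ts.combine_molecules([big, small])
    np.testing.assert_allclose(flipped.mean_displacement, combined.mean_displacement)
    alone = ts.combine_molecules([small])
    np.testing.assert_allclose(alone.mean_displacement, small.mean_displacement)


def test_combining_mixed_alignments_fails():
    tau = np.arange(10) * DT
    fwd = EnsembleAverage("forward", tau, np.zeros(10), 1, 1, 0.5)
    rev = EnsembleAverage("reverse", -tau[::-1], np.zeros(10), 1, 1, 0.5)
    with pytest.raises(ts.AnalysisError):
        ts.combine_molecules([fwd, rev])


def constructed_forward(plateau=4.41, baseline=0.0, span=0.5, pad=0.25):
    n_pad, n_span = int(pad * FS), int(span * FS)
    tau = np.arange(-n_pad, n_span + 1) * DT
    y = np.where(tau < 0, baseline, plateau)
    return EnsembleAverage("forward", tau, y.astype(float), n_events=100,
                           n_molecules=1, extension_span=span)


def test_total_step_on_constructed_average():
    d_total, baseline = ts.measure_total_step(constructed_forward(4.41))
    assert d_total == pytest.approx(4.41, abs=1e-9)
    assert baseline == pytest.approx(0.0, abs=1e-9)


def test_total_step_of_flat_trace_is_zero():
    d_total, _ = ts.measure_total_step(constructed_forward(0.0, 0.0))
    assert d_total == pytest.approx(0.0, abs=1e-9)


def test_total_step_invariant_under_common_offset():
    ens = constructed_forward(4.41)
    shifted = EnsembleAverage("forward", ens.tau, ens.mean_displacement + 5.0,
                              ens.n_events, ens.n_molecules, ens.extension_span)
    d_plain, _ = ts.measure_total_step(ens)
    d_shift, _ = ts.measure_total_step(shifted)
    assert d_shift == pytest.approx(d_plain, abs=1e-9)


def constructed_reverse(ext_level, span=0.5, pad=0.25):
    n_pad, n_span = int(pad * FS), int(span * FS)
    tau = np.arange(-n_span, n_pad + 1) * DT
    y = np.full(tau.size, float(ext_level))
    return EnsembleAverage("reverse", tau, y, n_events=100, n_molecules=1,
                           extension_span=span)


def test_substep_arithmetic_reproduces_reference_decomposition():
    # reverse extension level d1 = 3.32 with d_total = 4.41 -> d2 = 1.09
    d1, d2, detected = ts.measure_substeps(constructed_reverse(3.32), 4.41, 0.0)
    assert d2 == pytest.approx(1.09, abs=1e-9)
    assert d1 == pytest.approx(3.32, abs=1e-9)
    assert d1 + d2 == pytest.approx(4.41, abs=1e-12)
    assert detected


def test_substep_below_floor_reported_not_detected():
    d1, d2, detected = ts.measure_substeps(constructed_reverse(4.36), 4.41, 0.0)
    assert abs(d2) < 0.2
    assert not detected
    _, d2_zero, _ = ts.measure_substeps(constructed_reverse(4.41), 4.41, 0.0)
    assert d2_zero == pytest.approx(0.0, abs=1e-9)


def test_forward_rise_fit_exact_on_noiseless_curve():
    span, pad = 0.5, 0.0
    tau = np.arange(0, int(span * FS)) * DT
    y = 3.32 + 1.09 * (1 - np.exp(-99.1 * tau))
    ens = EnsembleAverage("forward", tau, y, 100, 1, span)
    fit = ts.fit_rise(ens)
    assert fit.ok
    assert fit.k == pytest.approx(99.1, rel=1e-6)
    assert fit.amplitude == pytest.approx(1.09, rel=1e-6)


def test_reverse_rise_fit_exact_on_noiseless_curve():
    span = 1.0
    tau = -np.arange(0, int(span * FS))[::-1] * DT
    y = 3.32 + 1.09 * np.exp(-4.59 * np.abs(tau))
    ens = EnsembleAverage("reverse", tau, y, 100, 1, span)
    fit = ts.fit_rise(ens)
    assert fit.k == pytest.approx(4.59, rel=1e-6)
    assert fit.amplitude == pytest.approx(1.09, rel=1e-4)


def test_constant_series_rise_flagged_unidentifiable():
    tau = np.arange(0, 2000) * DT
    ens = EnsembleAverage("forward", tau, np.full(tau.size, 2.5), 10, 1, 0.2)
    fit = ts.fit_rise(ens)
    assert not fit.ok
    assert "unidentifiable" in fit.note


def test_single_step_reverse_extension_matches_forward_plateau():
    # Ideal single-step events: no rise before detachment, so the reverse
    # backward extension sits at the forward plateau.
    n = 60_000
    disp1, ev1 = plateau_event(1.0, 1.5, 1.3, n)
    disp2, ev2 = plateau_event(3.0, 3.4, 1.3, n)
    trace = make_trace(disp1 + disp2)
    fwd = ts.forward_average(trace, [ev1, ev2], extension_span=0.4, pad=0.1, dead_time=TD)
    rev = ts.reverse_average(trace, [ev1, ev2], extension_span=0.4, pad=0.1, dead_time=TD)
    d_total, baseline = ts.measure_total_step(fwd, baseline_halfwidth=0.05)
    d1, d2, detected = ts.measure_substeps(rev, d_total, baseline)
    assert d_total == pytest.approx(1.3, abs=1e-6)
    assert abs(d2) < 1e-6
    assert not detected


def test_two_substep_reverse_average_shows_pre_detachment_rise():
    # Construct events holding d1 = 3.0 then stepping to 4.0 before the end.
    n = 60_000
    disp = np.zeros(n)
    events = []
    for t0 in (1.0, 3.0):
        i0, im, i1 = int(t0 * FS), int((t0 + 0.2) * FS), int((t0 + 0.5) * FS)
        disp[i0:im] = 3.0
        disp[im:i1] = 4.0
        events.append(ts.Event(raw_start=t0 + 0.015, raw_end=t0 + 0.515,
                               refined_start=t0 - 0.75 * TD,
                               refined_end=t0 + 0.5 + 1.35 * TD))
    rev = ts.reverse_average(make_trace(disp), events, extension_span=0.6,
                             pad=0.05, dead_time=TD)
    i_late = np.argmin(np.abs(rev.tau + 0.1))
    i_early = np.argmin(np.abs(rev.tau + 0.55))
    assert rev.mean_displacement[i_late] == pytest.approx(4.0, abs=1e-9)
    assert rev.mean_displacement[i_early] == pytest.approx(3.0, abs=1e-9)


def test_compare_conditions_paired_difference(wt_recording):
    # Split one molecule's recording into halves analyzed independently:
    # identical generative conditions give a near-zero paired difference.
    _, trace, _ = wt_recording
    half = trace.duration / 2
    segments = [ts.ConditionSegment("first half", (0.0, half)),
                ts.ConditionSegment("second half", (half, trace.duration))]
    config = ts.PipelineConfig(min_events_per_molecule=5)
    per_condition, diffs = ts.compare_conditions(trace, segments, config)
    assert set(per_condition) == {"first half", "second half"}
    (delta,) = diffs.values()
    assert abs(delta) < 1.0


def test_compare_conditions_rejects_overlapping_segments(wt_recording):
    _, trace, _ = wt_recording
    bad = [ts.ConditionSegment("a", (0.0, 30.0)), ts.ConditionSegment("b", (20.0, 50.0))]
    with pytest.raises(ts.AnalysisError):
        ts.compare_conditions(trace, bad)


def test_three_segment_exchange_recovers_monotone_pattern():
    # Drug / washout / partial re-add: total strokes high -> low -> middle.
    amplitudes = {"drug": 3.42, "washout": 1.29, "partial": 2.2}
    pieces, segments, t0 = [], [], 0.0
    for name, amp in amplitudes.items():
        config = ts.preset_config("r712l", seed=71 + len(pieces), duration=60.0,
                                  molecule_id="mol-x")
        config.substep1 = amp
        trace, _ = ts.simulate_dumbbell(config)
        pieces.append(trace)
        segments.append(ts.ConditionSegment(name, (t0, t0 + 60.0)))
        t0 += 60.0
    full = ts.TrapTrace(
        sample_interval=pieces[0].sample_interval,
        bead_a=np.concatenate([p.bead_a for p in pieces]),
        bead_b=np.concatenate([p.bead_b for p in pieces]),
        molecule_id="mol-x",
    )
    config = ts.PipelineConfig(min_events_per_molecule=10, extension_span_s=1.0)
    per_condition, _ = ts.compare_conditions(full, segments, config)
    measured = {name: step.total_step for name, step in per_condition.items()}
    assert measured["drug"] > measured["partial"] > measured["washout"]
    assert measured["drug"] == pytest.approx(3.42, abs=0.5)
    assert measured["washout"] == pytest.approx(1.29, abs=0.4)
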