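"""Event-aligned ensemble averages of bead displacement and the working
stroke / substep / kinetics measurements made on them.

Forward averages align events at their refined starts, reverse averages at
their refined ends.  Beyond each event's far boundary the displacement is
extended with the level the molecule held just inside that boundary, so
events of different lengths can be averaged point-wise.  Every molecule
contributes with equal weight to combined averages.

Extension-level geometry.  Refined boundaries are deliberately shifted
outward by 0.75 dead times, and the centered covariance window makes the
80%-recovery crossing trail the true detachment by ~0.6 dead times, so a
level window flush with the refined boundary would average mostly unbound
baseline.  The level is therefore measured over a 0.25-dead-time window
placed *inside* the bound interval: 1.0 dead times inward of the refined
start and 1.6 dead times inward of the refined end (shift + crossing lag +
a small guard against crossing-time jitter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from .errors import AnalysisError
from .events import Event
from .trace import TrapTrace

#: Inward offsets (in dead times) of the extension-level window.
START_LEVEL_OFFSET = 1.0
END_LEVEL_OFFSET = 1.6
LEVEL_WIDTH = 0.25


@dataclass
class EnsembleAverage:
    """Point-wise mean displacement of aligned events.

    ``tau`` is time relative to the alignment point: zero at the refined
    start (forward) or refined end (reverse).
    """

    alignment: str                  # 'forward' | 'reverse'
    tau: np.ndarray
    mean_displacement: np.ndarray
    n_events: int
    n_molecules: int
    extension_span: float

    def __post_init__(self) -> None:
        if self.alignment not in ("forward", "reverse"):
            raise ValueError(f"alignment must be 'forward' or 'reverse', got {self.alignment!r}")
        if self.n_events < 1:
            raise ValueError("an ensemble average needs at least one event")


def event_displacement(
    trace: TrapTrace,
    event: Event,
    pad: float = 0.0,
    signal: str = "mean",
    sign: float = 1.0,
):
    """Displacement series over [refined_start - pad, refined_end + pad].

    Returns ``(times, values, truncated)``; ``truncated`` is set when the pad
    runs past either end of the trace. Baseline-unsubtracted.
    """
    disp = trace.displacement(signal=signal, sign=sign)
    dt = trace.sample_interval
    i0 = int(round((event.refined_start - pad) / dt))
    i1 = int(round((event.refined_end + pad) / dt))
    truncated = i0 < 0 or i1 > disp.size
    i0c, i1c = max(0, i0), min(disp.size, i1)
    return np.arange(i0c, i1c) * dt, disp[i0c:i1c], truncated


def _level(disp: np.ndarray, lo: int, hi: int) -> float:
    lo = max(0, lo)
    hi = min(disp.size, hi)
    if hi <= lo:
        mid = min(disp.size - 1, max(0, (lo + hi) // 2))
        return float(disp[mid])
    return float(disp[lo:hi].mean())


def _event_levels(disp, event, dt, dead_time):
    """Boundary levels and their anchor samples.

    Returns (start_level, start_anchor, end_level, end_anchor): the levels
    just inside the bound interval and the sample indices at which the
    backward/forward extensions take over.  Extending from the same anchor
    where the level is measured keeps the pre-attachment and post-detachment
    baseline that sits inside the outward-shifted refined bounds out of the
    averages.  Windows clamp to the event for short events.
    """
    i0 = int(round(event.refined_start / dt))
    i1 = int(round(event.refined_end / dt))
    wd = max(1, int(round(LEVEL_WIDTH * dead_time / dt)))
    s_lo = i0 + int(round(START_LEVEL_OFFSET * dead_time / dt))
    e_hi = i1 - int(round(END_LEVEL_OFFSET * dead_time / dt))
    s_lo = min(s_lo, i1 - wd)
    e_hi = max(e_hi, s_lo + wd)
    start_level = _level(disp, s_lo, s_lo + wd)
    end_level = _level(disp, e_hi - wd, e_hi)
    return start_level, s_lo, end_level, e_hi


def _aligned_average(
    trace, events, extension_span, pad, dead_time, signal, sign, alignment
) -> EnsembleAverage:
    if not events:
        raise AnalysisError("cannot ensemble-average zero events")
    disp = trace.displacement(signal=signal, sign=sign)
    dt = trace.sample_interval
    n = disp.size
    n_span = int(round(extension_span / dt))
    n_pad = int(round(pad / dt))
    if alignment == "forward":
        j = np.arange(-n_pad, n_span + 1)
    else:
        j = np.arange(-n_span, n_pad + 1)
    total = np.zeros(j.size)
    count = np.zeros(j.size)
    for ev in events:
        i0 = int(round(ev.refined_start / dt))
        i1 = int(round(ev.refined_end / dt))
        start_level, s_anchor, end_level, e_anchor = _event_levels(disp, ev, dt, dead_time)
        align_at = i0 if alignment == "forward" else i1
        idx = align_at + j
        inside_trace = (idx >= 0) & (idx < n)
        vals = np.where(inside_trace, disp[np.clip(idx, 0, n - 1)], 0.0)
        if alignment == "forward":
            # Beyond this event's end-level anchor (or the trace end), hold
            # the level the molecule had just before detaching.
            extended = (idx >= e_anchor) | (idx >= n)
            vals = np.where(extended, end_level, vals)
            valid = inside_trace | extended
        else:
            extended = (idx < s_anchor)
            vals = np.where(extended, start_level, vals)
            valid = (inside_trace & ~extended) | extended
            valid &= (idx < n) | extended
        total += np.where(valid, vals, 0.0)
        count += valid
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return EnsembleAverage(
        alignment=alignment,
        tau=j * dt,
        mean_displacement=mean,
        n_events=len(events),
        n_molecules=1,
        extension_span=extension_span,
    )


def forward_average(
    trace: TrapTrace,
    events: list[Event],
    extension_span: float = 0.5,
    pad: float = 0.25,
    dead_time: float = 0.015,
    signal: str = "mean",
    sign: float = 1.0,
) -> EnsembleAverage:
    """Time-forward ensemble average (events aligned at refined starts)."""
    return _aligned_average(trace, events, extension_span, pad, dead_time, signal, sign, "forward")


def reverse_average(
    trace: TrapTrace,
    events: list[Event],
    extension_span: float = 0.5,
    pad: float = 0.25,
    dead_time: float = 0.015,
    signal: str = "mean",
    sign: float = 1.0,
) -> EnsembleAverage:
    """Time-reversed ensemble average (events aligned at refined ends)."""
    return _aligned_average(trace, events, extension_span, pad, dead_time, signal, sign, "reverse")


def combine_molecules(per_molecule: list[EnsembleAverage]) -> EnsembleAverage:
    """Equal-weight mean over molecules (each molecule counts once,
    regardless of how many events it contributed)."""
    if not per_molecule:
        raise AnalysisError("no ensemble averages to combine")
    alignment = per_molecule[0].alignment
    tau = per_molecule[0].tau
    for ens in per_molecule[1:]:
        if ens.alignment != alignment:
            raise AnalysisError("cannot combine forward and reverse averages")
        if ens.tau.shape != tau.shape or not np.allclose(ens.tau, tau):
            raise AnalysisError("ensemble averages must share one tau grid")
    stack = np.vstack([ens.mean_displacement for ens in per_molecule])
    return EnsembleAverage(
        alignment=alignment,
        tau=tau,
        mean_displacement=np.nanmean(stack, axis=0),
        n_events=sum(ens.n_events for ens in per_molecule),
        n_molecules=sum(ens.n_molecules for ens in per_molecule),
        extension_span=per_molecule[0].extension_span,
    )


def measure_baseline(
    forward: EnsembleAverage,
    smooth_window: float = 0.008,
    search_halfwidth: float = 0.2,
) -> float:
    """Pre-attachment baseline: minimum of the 8-ms-smoothed ensemble average
    within +/-0.2 s of the alignment zero."""
    dt = float(forward.tau[1] - forward.tau[0])
    w = max(1, int(round(smooth_window / dt)))
    y = forward.mean_displacement
    finite = np.isfinite(y)
    smoothed = uniform_filter1d(np.where(finite, y, 0.0), size=w, mode="nearest")
    norm = uniform_filter1d(finite.astype(float), size=w, mode="nearest")
    with np.errstate(invalid="ignore"):
        smoothed = smoothed / np.where(norm > 0, norm, np.nan)
    mask = (np.abs(forward.tau) <= search_halfwidth) & np.isfinite(smoothed)
    if not mask.any():
        raise AnalysisError("no samples within the baseline search window")
    return float(np.nanmin(smoothed[mask]))


def _plateau(ens: EnsembleAverage, fraction: float = 0.2) -> float:
    """Mean over the outer `fraction` of the extension span (the fully
    extended region)."""
    if ens.alignment == "forward":
        mask = ens.tau >= (1.0 - fraction) * ens.extension_span
    else:
        mask = ens.tau <= -(1.0 - fraction) * ens.extension_span
    mask &= np.isfinite(ens.mean_displacement)
    if mask.sum() < 10:
        raise AnalysisError("extension region shorter than 10 samples")
    return float(ens.mean_displacement[mask].mean())


def measure_total_step(
    forward: EnsembleAverage,
    plateau_fraction: float = 0.2,
    smooth_window: float = 0.008,
    baseline_halfwidth: float = 0.2,
) -> tuple[float, float]:
    """(d_total, baseline): forward extension plateau minus the smoothed
    pre-attachment minimum."""
    if forward.alignment != "forward":
        raise AnalysisError("measure_total_step needs a forward average")
    baseline = measure_baseline(forward, smooth_window, baseline_halfwidth)
    return _plateau(forward, plateau_fraction) - baseline, baseline


def measure_substeps(
    reverse: EnsembleAverage,
    d_total: float,
    baseline: float,
    plateau_fraction: float = 0.2,
    resolution_floor: float = 0.2,
) -> tuple[float, float, bool]:
    """(d1, d2, d2_detected).

    d2 = d_total - (reverse backward-extension level - baseline); a |d2|
    below the resolution floor (default 0.2 nm) is reported as not detected.
    """
    if reverse.alignment != "reverse":
        raise AnalysisError("measure_substeps needs a reverse average")
    ext_level = _plateau(reverse, plateau_fraction)
    d2 = d_total - (ext_level - baseline)
    d1 = d_total - d2
    return d1, d2, bool(abs(d2) >= resolution_floor)


@dataclass
class RiseFit:
    """Single-exponential fit to the rising phase of an ensemble average."""

    k: float
    k_se: float
    amplitude: float
    offset: float
    ok: bool = True
    note: str = ""


def fit_rise(
    ensemble: EnsembleAverage,
    fit_start: float = 0.0,
    fit_window: float | None = None,
    window_factor: float = 5.0,
    amplitude_floor: float = 0.05,
    asymptote: float | str | None = None,
    nuisance_rate: float | None = None,
) -> RiseFit:
    """Fit y = a + b*(1 - exp(-k*tau)) (forward) or y = a + b*exp(-k*|tau|)
    (reverse) to the ensemble average.

    ``fit_start`` excludes the region within the covariance lag of the
    alignment point (in seconds; 0 fits everything).  Both models are linear
    in (a, b) at fixed k, so the rate is initialized by an exact profile
    scan: linear least squares on the basis {1, exp(-k*s)} over a log-spaced
    rate grid, keeping the rate with the smallest residual.  The final
    nonlinear fit is restricted to ``window_factor``/k past the start, where
    the exponential carries information.  A near-zero amplitude leaves the
    rate unidentifiable and is flagged rather than fitted.

    When ``asymptote`` is given, the fit's limiting level (a + b forward, a
    reverse) is pinned to it; ``asymptote='local'`` pins it to the mean over
    the final fifth of the fit window.  Pinning removes the strong
    asymptote-rate tradeoff of exponential fits over a few 1/k of data, and
    the local pin tracks the fit window's own plateau rather than the far
    extension level.

    ``nuisance_rate`` adds a fixed-rate exponential term with a free
    amplitude to the model.  A forward average carries a small component at
    the detachment rate (the still-bound fraction decays while extension
    levels hold their boundary values), and absorbing it into a known-rate
    nuisance term keeps it out of the fast rise rate.
    """
    y_all = ensemble.mean_displacement
    if ensemble.alignment == "forward":
        s_all = ensemble.tau
    else:
        s_all = -ensemble.tau  # time before detachment, positive
    use = (s_all >= fit_start) & np.isfinite(y_all)
    if fit_window is not None:
        use &= s_all <= fit_start + fit_window
    s, y = s_all[use], y_all[use]
    if s.size < 10:
        raise AnalysisError("fewer than 10 samples in the rise-fit window")
    order = np.argsort(s)
    s, y = s[order], y[order]

    far = y[s >= s[-1] - 0.2 * (s[-1] - s[0])].mean()   # asymptote estimate
    if asymptote == "local":
        asymptote = far
    z = (far - y) if ensemble.alignment == "forward" else (y - far)
    amp0 = z[: max(3, z.size // 50)].mean()
    if not np.isfinite(amp0) or abs(amp0) < amplitude_floor:
        return RiseFit(k=float("nan"), k_se=float("nan"), amplitude=0.0, offset=far,
                       ok=False, note="amplitude below resolution; rate unidentifiable")

    # Profile scan: solve the amplitude(s) in closed form on a rate grid.
    s0 = s - s[0]
    slow = np.exp(-nuisance_rate * s0) if nuisance_rate is not None else None
    best_k, best_sse = None, np.inf
    for k in np.geomspace(0.2, 3000.0, 80):
        e = np.exp(-k * s0)
        if asymptote is None:
            columns = [np.ones_like(s0), e]
            if slow is not None:
                columns.append(slow)
            basis = np.column_stack(columns)
            coef, res, *_ = np.linalg.lstsq(basis, y, rcond=None)
            sse = res[0] if res.size else np.sum((basis @ coef - y) ** 2)
        else:
            r = asymptote - y   # residual from the pinned limit, both models
            if slow is None:
                b_hat = (e @ r) / (e @ e)
                sse = np.sum((r - b_hat * e) ** 2)
            else:
                basis = np.column_stack([e, slow])
                coef, res, *_ = np.linalg.lstsq(basis, r, rcond=None)
                sse = res[0] if res.size else np.sum((basis @ coef - r) ** 2)
        if sse < best_sse:
            best_k, best_sse = k, sse
    k0 = best_k

    # The adaptive 5/k shrink concentrates the fit where a lone exponential
    # carries information; with an explicit window or a slow nuisance term
    # the full window is required (over a fraction of 1/k_nuisance the
    # nuisance column is near-constant and degenerate with the offset).
    if fit_window is not None or nuisance_rate is not None:
        win = np.ones_like(s, dtype=bool)
    else:
        win = s <= s[0] + window_factor / k0
        if win.sum() < 10:
            win = np.ones_like(s, dtype=bool)
    sw, yw = s[win], y[win]

    forward = ensemble.alignment == "forward"

    def fast_term(t, b, k):
        return b * (1.0 - np.exp(-k * t)) if forward else b * np.exp(-k * t)

    def model(t, *params):
        if asymptote is None:
            a, b, k = params[:3]
        else:
            b, k = params[:2]
            a = asymptote - b if forward else asymptote
        out = a + fast_term(t, b, k)
        if nuisance_rate is not None:
            out = out + params[-1] * np.exp(-nuisance_rate * (t - sw[0]))
        return out

    a0 = yw[0] if forward else far
    p0 = ([a0, amp0] if asymptote is None else [abs(amp0)])
    lo = [-np.inf] * len(p0) + [1e-3]
    hi = [np.inf] * len(p0) + [1e5]
    p0 = p0 + [None]  # placeholder for k, filled per start
    if nuisance_rate is not None:
        lo, hi = lo + [-np.inf], hi + [np.inf]

    last_exc = None
    for k_start in (k0, k0 * 3, k0 / 3):
        params0 = [v for v in p0[:-1]] + [k_start]
        if nuisance_rate is not None:
            params0 = params0 + [0.0]
        try:
            popt, pcov = curve_fit(model, sw, yw, p0=params0, bounds=(lo, hi),
                                   maxfev=20000)
            if asymptote is None:
                a, b, k = popt[:3]
                k_index = 2
            else:
                b, k = popt[:2]
                a = asymptote - b if forward else asymptote
                k_index = 1
            k_se = float(np.sqrt(pcov[k_index, k_index]))
            return RiseFit(k=float(k), k_se=k_se, amplitude=float(b), offset=float(a))
        except Exception as exc:
            last_exc = exc
    raise AnalysisError(f"rise fit did not converge after multi-start: {last_exc}")


@dataclass
class StepMeasurement:
    """Working-stroke decomposition of one molecule or a combined ensemble."""

    total_step: float
    substep1: float
    substep2: float
    substep2_detected: bool
    k_forward: float
    k_forward_se: float
    k_reverse: float
    k_reverse_se: float
    baseline: float
    n_events: int = 0
    n_molecules: int = 1
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "d_total_nm": self.total_step,
            "d1_nm": self.substep1,
            "d2_nm": self.substep2,
            "d2_detected": self.substep2_detected,
            "k_forward_s": self.k_forward,
            "k_forward_se": self.k_forward_se,
            "k_reverse_s": self.k_reverse,
            "k_reverse_se": self.k_reverse_se,
            "baseline_nm": self.baseline,
            "n_events": self.n_events,
            "n_molecules": self.n_molecules,
            "flags": list(self.flags),
        }


def measure_steps(
    forward: EnsembleAverage,
    reverse: EnsembleAverage,
    dead_time: float,
    resolution_floor: float = 0.2,
    forward_fit_start_dead_times: float = 1.0,
    reverse_fit_start_dead_times: float = 1.6,
    forward_fit_window: float | None = 0.3,
    reverse_fit_window: float | None = None,
) -> StepMeasurement:
    """Full working-stroke measurement from a forward/reverse average pair.

    The rise fits start past the covariance lag around the alignment point
    (shift + crossing lag, in dead times); an exponential restricted to a
    shifted window keeps the same rate, so the delayed start trades a little
    amplitude for freedom from boundary smearing.
    """
    d_total, baseline = measure_total_step(forward)
    d1, d2, detected = measure_substeps(reverse, d_total, baseline,
                                        resolution_floor=resolution_floor)
    flags = []
    rev = fit_rise(reverse, fit_start=reverse_fit_start_dead_times * dead_time,
                   fit_window=reverse_fit_window)
    slow = rev.k if (rev.ok and np.isfinite(rev.k)) else None
    fwd = fit_rise(forward, fit_start=forward_fit_start_dead_times * dead_time,
                   fit_window=forward_fit_window, nuisance_rate=slow)
    if not fwd.ok:
        flags.append(f"forward rise: {fwd.note}")
    if not rev.ok:
        flags.append(f"reverse rise: {rev.note}")
    return StepMeasurement(
        total_step=d_total,
        substep1=d1,
        substep2=d2,
        substep2_detected=detected,
        k_forward=fwd.k,
        k_forward_se=fwd.k_se,
        k_reverse=rev.k,
        k_reverse_se=rev.k_se,
        baseline=baseline,
        n_events=forward.n_events,
        n_molecules=forward.n_molecules,
        flags=flags,
    )


@dataclass
class ConditionSegment:
    """A time range of a parent trace recorded under one solution condition."""

    condition: str
    time_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.time_range[1] <= self.time_range[0]:
            raise ValueError("time_range must be an increasing (start, end) pair")


def compare_conditions(trace: TrapTrace, segments: list[ConditionSegment], config=None):
    """Paired per-condition working-stroke measurements on one molecule.

    Runs the full detection -> ensemble -> step pipeline independently on
    each segment of the parent trace (the buffer-exchange experiment), and
    returns ``(per_condition, differences)`` where differences map
    consecutive condition pairs to the change in total step.  Segments with
    fewer than 10 events are flagged but still reported.
    """
    from .pipeline import PipelineConfig, analyze_molecule

    if len(segments) < 2:
        raise AnalysisError("compare_conditions needs at least 2 segments")
    for i in range(len(segments) - 1):
        if segments[i].time_range[1] > segments[i + 1].time_range[0]:
            raise AnalysisError("condition segments must not overlap")
    config = config or PipelineConfig(min_events_per_molecule=1)
    per_condition: dict[str, StepMeasurement] = {}
    for seg in segments:
        sub = trace.segment(*seg.time_range, condition=seg.condition)
        result = analyze_molecule(sub, config)
        step = result.steps
        if step is not None and step.n_events < 10:
            step.flags.append(f"only {step.n_events} events in segment '{seg.condition}'")
        per_condition[seg.condition] = step
    names = [seg.condition for seg in segments]
    differences = {
        f"{names[i + 1]} - {names[i]}":
            per_condition[names[i + 1]].total_step - per_condition[names[i]].total_step
        for i in range(len(names) - 1)
        if per_condition[names[i]] is not None and per_condition[names[i + 1]] is not None
    }
    return per_condition, differences
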