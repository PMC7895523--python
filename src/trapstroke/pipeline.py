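"""The full per-molecule and multi-molecule analysis chain:

covariance -> peak decomposition -> separation gate -> detection ->
refinement -> event-count gate -> ensemble averages -> working-stroke
measurement -> dwell-time MLE -> equal-molecule-weight combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _pkg_version
from .config import PipelineConfig
from .covariance import CovariancePeaks, compute_covariance, fit_covariance_peaks
from .ensembles import (EnsembleAverage, StepMeasurement, combine_molecules,
                        forward_average, measure_steps, reverse_average)
from .errors import AnalysisError, MoleculeNotAnalyzableError
from .events import Event, detect_events, refine_events
from .lifetimes import LifetimeFit, fit_lifetimes, select_model, bootstrap_ci
from .trace import TrapTrace

logger = logging.getLogger("trapstroke")


@dataclass
class MoleculeResult:
    """Everything the pipeline measured (or logged) for one molecule."""

    molecule_id: str
    included: bool
    exclusion_reason: str | None = None
    n_events: int = 0
    events: list[Event] = field(default_factory=list)
    peaks: CovariancePeaks | None = None
    forward: EnsembleAverage | None = None
    reverse: EnsembleAverage | None = None
    steps: StepMeasurement | None = None
    lifetime_fit: LifetimeFit | None = None
    log: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    """Per-molecule and combined results plus the exact configuration echo."""

    config: dict
    software_version: str
    seed: int
    molecules: list[MoleculeResult]
    combined_steps: StepMeasurement | None = None
    combined_lifetime_fit: LifetimeFit | None = None

    def to_dict(self) -> dict:
        return {
            "software_version": self.software_version,
            "seed": self.seed,
            "config": self.config,
            "molecules": [
                {
                    "molecule_id": m.molecule_id,
                    "included": m.included,
                    "exclusion_reason": m.exclusion_reason,
                    "n_events": m.n_events,
                    "steps": m.steps.to_dict() if m.steps else None,
                    "lifetimes": m.lifetime_fit.to_dict() if m.lifetime_fit else None,
                    "log": m.log,
                }
                for m in self.molecules
            ],
            "combined": {
                "steps": self.combined_steps.to_dict() if self.combined_steps else None,
                "lifetimes": (self.combined_lifetime_fit.to_dict()
                              if self.combined_lifetime_fit else None),
            },
        }


def _select_window(trace: TrapTrace, config: PipelineConfig):
    """Covariance window: fixed, or the smallest candidate that still
    separates the bound/unbound peaks."""
    if not config.auto_window_search:
        cov = compute_covariance(trace, config.covariance_window_s)
        return cov, fit_covariance_peaks(cov, method=config.peak_fit_method)
    last = None
    for w_ms in sorted(config.window_candidates_ms):
        cov = compute_covariance(trace, w_ms * 1e-3)
        peaks = fit_covariance_peaks(cov, method=config.peak_fit_method)
        last = (cov, peaks)
        if peaks.separated:
            logger.info("window search: %s ms separates the peaks", w_ms)
            return cov, peaks
    return last


def analyze_molecule(trace: TrapTrace, config: PipelineConfig | None = None) -> MoleculeResult:
    """Run the per-molecule chain; gate failures yield an excluded result
    with a machine-readable reason instead of raising."""
    config = config or PipelineConfig()
    result = MoleculeResult(molecule_id=trace.molecule_id, included=False)
    cov, peaks = _select_window(trace, config)
    result.peaks = peaks
    if not peaks.separated:
        result.exclusion_reason = "unseparated_peaks"
        logger.info("%s: excluded (bound/unbound covariance peaks not separated)",
                    trace.molecule_id)
        return result
    try:
        raw = detect_events(cov, peaks, molecule_id=trace.molecule_id)
    except MoleculeNotAnalyzableError:
        result.exclusion_reason = "unseparated_peaks"
        return result
    events = refine_events(
        cov, peaks, raw,
        start_threshold_fraction=config.start_threshold_fraction,
        end_threshold_fraction=config.end_threshold_fraction,
        shift_fraction_of_dead_time=config.shift_fraction_of_dead_time,
        near_window_factor=config.near_window_factor,
        min_duration_dead_times=config.min_duration_dead_times,
        log=result.log,
    )
    result.events = events
    result.n_events = len(events)
    logger.info("%s: %d raw events, %d refined", trace.molecule_id, len(raw), len(events))
    if len(events) < config.min_events_per_molecule:
        result.exclusion_reason = "too_few_events"
        logger.info("%s: excluded (%d events < %d required)",
                    trace.molecule_id, len(events), config.min_events_per_molecule)
        return result

    dead_time = cov.dead_time
    kwargs = dict(extension_span=config.extension_span_s, pad=config.pad_s,
                  dead_time=dead_time, signal=config.displacement_signal,
                  sign=config.displacement_sign)
    result.forward = forward_average(trace, events, **kwargs)
    result.reverse = reverse_average(trace, events, **kwargs)
    result.steps = measure_steps(
        result.forward, result.reverse, dead_time,
        resolution_floor=config.resolution_floor_nm,
        forward_fit_start_dead_times=config.forward_fit_start_dead_times,
        reverse_fit_start_dead_times=config.reverse_fit_start_dead_times,
        forward_fit_window=config.forward_fit_window_s,
        reverse_fit_window=config.reverse_fit_window_s,
    )

    durations = np.array([ev.duration for ev in events])
    try:
        fits = fit_lifetimes(durations, dead_time=dead_time,
                             max_order=config.mle_max_order,
                             n_starts=config.mle_n_starts, seed=config.seed)
        if config.mle_max_order >= 2:
            chosen, _ = select_model(fits[1], fits[2], alpha=config.model_selection_alpha)
        else:
            chosen = fits[1]
        if config.run_bootstrap:
            bootstrap_ci(durations, dead_time, chosen, n_boot=config.n_boot,
                         seed=config.seed)
        result.lifetime_fit = chosen
    except AnalysisError as exc:
        result.log.append(f"lifetime fit skipped: {exc}")
    result.included = True
    return result


def run_pipeline(traces: list[TrapTrace], config: PipelineConfig | None = None) -> RunReport:
    """Analyze every molecule, then combine included molecules with equal
    weight. Deterministic given ``config.seed``. Raises if no molecule
    survives the gates."""
    config = config or PipelineConfig()
    results = [analyze_molecule(trace, config) for trace in traces]
    included = [r for r in results if r.included]
    report = RunReport(
        config=config.to_dict(),
        software_version=_pkg_version,
        seed=config.seed,
        molecules=results,
    )
    if not included:
        reasons = {r.molecule_id: r.exclusion_reason for r in results}
        raise AnalysisError(f"no molecule passed the analysis gates: {reasons}")

    dead_time = config.covariance_window_s / 2.0
    fwd = combine_molecules([r.forward for r in included])
    rev = combine_molecules([r.reverse for r in included])
    report.combined_steps = measure_steps(
        fwd, rev, dead_time,
        resolution_floor=config.resolution_floor_nm,
        forward_fit_start_dead_times=config.forward_fit_start_dead_times,
        reverse_fit_start_dead_times=config.reverse_fit_start_dead_times,
        forward_fit_window=config.forward_fit_window_s,
        reverse_fit_window=config.reverse_fit_window_s,
    )

    pooled = np.concatenate([[ev.duration for ev in r.events] for r in included])
    try:
        fits = fit_lifetimes(pooled, dead_time=dead_time,
                             max_order=config.mle_max_order,
                             n_starts=config.mle_n_starts, seed=config.seed)
        if config.mle_max_order >= 2:
            chosen, _ = select_model(fits[1], fits[2], alpha=config.model_selection_alpha)
        else:
            chosen = fits[1]
        if config.run_bootstrap:
            bootstrap_ci(pooled, dead_time, chosen, n_boot=config.n_boot, seed=config.seed)
        report.combined_lifetime_fit = chosen
    except AnalysisError as exc:
        logger.info("combined lifetime fit skipped: %s", exc)
    return report
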