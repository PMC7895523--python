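"""Threshold-crossing event detection on the covariance signal and the
two-step refinement of event boundaries.

Detection demands a full excursion of the covariance from the unbound-peak
mean down to the bound-peak mean and back, which suppresses false positives
from partial dips.  Refinement then moves each boundary to the nearer
halfway (start) or 80%-recovered (end) crossing and applies the +/-0.75
dead-time shift that compensates the lag of the finite averaging window.
All event times are seconds from trace start, sample-aligned, intervals
half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .covariance import CovariancePeaks, CovarianceSeries
from .errors import MoleculeNotAnalyzableError


@dataclass
class Event:
    """One actomyosin attachment interval (raw and refined bounds)."""

    raw_start: float
    raw_end: float
    refined_start: float
    refined_end: float
    molecule_id: str = ""

    @property
    def duration(self) -> float:
        return self.refined_end - self.refined_start

    @property
    def raw_duration(self) -> float:
        return self.raw_end - self.raw_start


def detect_events(cov: CovarianceSeries, peaks: CovariancePeaks,
                  molecule_id: str = "") -> list[Event]:
    """Raw events: excursions from >= unbound mean to <= bound mean and back.

    raw_start is the first sample at or below the bound mean inside the
    excursion, raw_end the first subsequent sample at or above the unbound
    mean (equality counts as crossed).
    """
    if not peaks.separated:
        raise MoleculeNotAnalyzableError(
            "bound/unbound covariance peaks are not separated; molecule not analyzable"
        )
    v = cov.values
    dt = cov.sample_interval
    b_idx = np.flatnonzero(v <= peaks.bound_mean)
    u_idx = np.flatnonzero(v >= peaks.unbound_mean)
    events: list[Event] = []
    if b_idx.size == 0 or u_idx.size == 0:
        return events
    cursor = u_idx[0]  # must visit the unbound level before the first event
    while True:
        j = np.searchsorted(b_idx, cursor + 1)
        if j >= b_idx.size:
            break
        start = b_idx[j]
        k = np.searchsorted(u_idx, start + 1)
        if k >= u_idx.size:
            break
        end = u_idx[k]
        events.append(Event(raw_start=start * dt, raw_end=end * dt,
                            refined_start=start * dt, refined_end=end * dt,
                            molecule_id=molecule_id))
        cursor = end
    return events


def refine_events(
    cov: CovarianceSeries,
    peaks: CovariancePeaks,
    events: list[Event],
    *,
    start_threshold_fraction: float = 0.5,
    end_threshold_fraction: float = 0.8,
    shift_fraction_of_dead_time: float = 0.75,
    near_window_factor: float = 1.5,
    min_duration_dead_times: float = 1.0,
    log: list[str] | None = None,
) -> list[Event]:
    """Refine raw boundaries, shift them by -/+ 0.75 dead times, drop events
    shorter than the dead time, and drop overlapping pairs.

    Start: the crossing below bound + f_start*(unbound-bound) that leads into
    the raw start, i.e. the beginning of the contiguous below-threshold run
    containing it (capped at 2x the near window).  End: the first crossing
    above bound + f_end*(unbound-bound) after the event's last
    bound-level sample (the end rule mirrors the start rule).  On a clean
    signal both coincide with the nearest threshold crossings; anchoring on
    contiguous runs and bound-level evidence keeps isolated noise dips and
    noise-delayed raw bounds from teleporting a boundary.
    """
    v = cov.values
    dt = cov.sample_interval
    n = v.size
    t_d = cov.dead_time
    span = peaks.unbound_mean - peaks.bound_mean
    thr_start = peaks.bound_mean + start_threshold_fraction * span
    thr_end = peaks.bound_mean + end_threshold_fraction * span
    shift = shift_fraction_of_dead_time * t_d

    refined: list[Event] = []
    for ev in events:
        cap = max(1, int(round(2.0 * near_window_factor * t_d / dt)))

        i_start = int(round(ev.raw_start / dt))
        lo = max(0, i_start - cap)
        run = v[lo : i_start + 1] <= thr_start
        above = np.flatnonzero(~run)
        start_idx = lo + (above[-1] + 1 if above.size else 0)

        i_end = int(round(ev.raw_end / dt))
        inside = v[i_start : i_end + 1] <= peaks.bound_mean
        anchors = np.flatnonzero(inside)
        anchor = i_start + (anchors[-1] if anchors.size else 0)
        after = np.flatnonzero(v[anchor : min(n, i_end + cap) + 1] >= thr_end)
        end_idx = anchor + after[0] if after.size else i_end

        new = replace(ev, refined_start=start_idx * dt - shift,
                      refined_end=end_idx * dt + shift)
        if new.duration < min_duration_dead_times * t_d:
            if log is not None:
                log.append(
                    f"dropped event at {ev.raw_start:.4f}s: refined duration "
                    f"{new.duration * 1e3:.1f} ms < dead time {t_d * 1e3:.1f} ms"
                )
            continue
        refined.append(new)

    # The +/- shifts can make neighbours overlap; drop both members of an
    # overlapping pair (conservative: their boundaries are unreliable).
    keep = np.ones(len(refined), dtype=bool)
    for i in range(len(refined) - 1):
        if refined[i].refined_end > refined[i + 1].refined_start:
            keep[i] = keep[i + 1] = False
            if log is not None:
                log.append(
                    f"dropped overlapping pair at {refined[i].raw_start:.4f}s / "
                    f"{refined[i + 1].raw_start:.4f}s after boundary shifts"
                )
    return [ev for ev, k in zip(refined, keep) if k]


def match_events(truth, detected, min_overlap: float = 0.5):
    """Interval matching of detected events against ground truth.

    A true event is recovered when some detected interval overlaps at least
    ``min_overlap`` of its duration (two true attachments separated by less
    than the averaging window may be covered by one detected excursion, so
    the matching is not forced one-to-one).  Returns (recall,
    false_positive_rate, matched_pairs); the FP rate is the fraction of
    detected events overlapping no true event at all.
    """
    pairs = []
    touched = set()
    for ti, tr in enumerate(truth):
        t0 = getattr(tr, "attach_time", None)
        t1 = getattr(tr, "detach_time", None)
        if t0 is None:
            t0, t1 = tr
        best, best_ov = None, 0.0
        for di, ev in enumerate(detected):
            ov = min(t1, ev.refined_end) - max(t0, ev.refined_start)
            if ov > 0:
                touched.add(di)
            if ov > best_ov:
                best, best_ov = di, ov
        if best is not None and best_ov >= min_overlap * (t1 - t0):
            pairs.append((ti, best))
    recall = len(pairs) / len(truth) if truth else 1.0
    fpr = (len(detected) - len(touched)) / len(detected) if detected else 0.0
    return recall, fpr, pairs


def events_to_frame(events: list[Event]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "molecule_id": [ev.molecule_id for ev in events],
            "event_index": np.arange(len(events)),
            "raw_start_s": [ev.raw_start for ev in events],
            "raw_end_s": [ev.raw_end for ev in events],
            "refined_start_s": [ev.refined_start for ev in events],
            "refined_end_s": [ev.refined_end for ev in events],
            "duration_s": [ev.duration for ev in events],
        }
    )


def write_events_csv(events: list[Event], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[Event]:
    table = pd.read_csv(path)
    return [
        Event(
            raw_start=row.raw_start_s,
            raw_end=row.raw_end_s,
            refined_start=row.refined_start_s,
            refined_end=row.refined_end_s,
            molecule_id=str(row.molecule_id),
        )
        for row in table.itertuples()
    ]
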