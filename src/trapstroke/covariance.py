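"""Sliding-window bead-bead covariance and its bound/unbound decomposition.

The windowed covariance of the two bead positions is high while the dumbbell
fluctuates freely and drops while myosin is attached; its value distribution
over a recording is bimodal and is decomposed into two Gaussians.  A molecule
is analyzable only when the peaks separate: unbound mean minus its SD must
exceed bound mean plus its SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import welch

from . import physics
from .errors import AnalysisError
from .trace import TrapTrace


@dataclass
class CovarianceSeries:
    """Windowed covariance sampled at every trace sample.

    ``dead_time`` — the minimum detectable event duration — is half the
    averaging window by construction.
    """

    times: np.ndarray
    values: np.ndarray
    window: float
    sample_interval: float

    @property
    def dead_time(self) -> float:
        return self.window / 2.0


def compute_covariance(trace_or_a, window: float | None = None, *, b=None,
                       sample_interval: float | None = None) -> CovarianceSeries:
    """Centered sliding-window sample covariance of the two bead positions.

    Accepts a :class:`TrapTrace` or two raw arrays (``compute_covariance(a,
    window, b=b, sample_interval=dt)``).  Edge samples use the truncated
    available window.  Both series are demeaned globally first, which leaves
    every windowed covariance unchanged but keeps the accumulating sums small;
    the result is therefore exactly invariant to constant offsets.
    """
    if isinstance(trace_or_a, TrapTrace):
        a, b = trace_or_a.bead_a, trace_or_a.bead_b
        dt = trace_or_a.sample_interval
    else:
        a = np.asarray(trace_or_a, dtype=float)
        b = np.asarray(b, dtype=float)
        if sample_interval is None:
            raise ValueError("sample_interval is required with raw arrays")
        dt = sample_interval
    if window is None:
        raise ValueError("window (seconds) is required")
    n = a.size
    w = int(round(window / dt))
    if w < 3:
        raise AnalysisError(f"covariance window must span >= 3 samples, got {w}")
    if w > n:
        raise AnalysisError(f"covariance window ({w} samples) longer than trace ({n})")

    a = a - a.mean()
    b = b - b.mean()
    # Prefix sums with a leading zero; window for sample i is
    # [i - w//2, i - w//2 + w) clipped to the trace.
    sa = np.concatenate(([0.0], np.cumsum(a)))
    sb = np.concatenate(([0.0], np.cumsum(b)))
    sab = np.concatenate(([0.0], np.cumsum(a * b)))
    lo = np.arange(n) - w // 2
    hi = lo + w
    np.clip(lo, 0, n, out=lo)
    np.clip(hi, 0, n, out=hi)
    cnt = (hi - lo).astype(float)
    ssa = sa[hi] - sa[lo]
    ssb = sb[hi] - sb[lo]
    ssab = sab[hi] - sab[lo]
    values = (ssab - ssa * ssb / cnt) / (cnt - 1.0)
    return CovarianceSeries(
        times=np.arange(n) * dt, values=values, window=w * dt, sample_interval=dt
    )


@dataclass
class CovariancePeaks:
    """Two-Gaussian decomposition of the covariance value distribution."""

    bound_mean: float
    bound_sd: float
    unbound_mean: float
    unbound_sd: float
    mixture_weight: float      # fraction of samples in the bound component
    converged: bool = True
    log_likelihood: float = float("nan")

    @property
    def separated(self) -> bool:
        return (self.unbound_mean - self.unbound_sd) > (self.bound_mean + self.bound_sd)

    @property
    def halfway(self) -> float:
        return 0.5 * (self.bound_mean + self.unbound_mean)


_MAX_EM_SAMPLES = 100_000


def fit_covariance_peaks(cov: CovarianceSeries, method: str = "em") -> CovariancePeaks:
    """Decompose the covariance distribution into bound + unbound Gaussians.

    ``method='em'`` runs expectation-maximization (k-means initialization,
    multiple restarts); ``method='histogram'`` least-squares fits a
    two-Gaussian model to a 200-bin histogram.  The lower-mean component is
    the bound peak.
    """
    values = np.asarray(cov.values, dtype=float)
    if values.size < 1000:
        raise AnalysisError(f"need >= 1000 covariance samples to fit peaks, got {values.size}")
    if method == "em":
        return _fit_peaks_em(values)
    if method == "histogram":
        return _fit_peaks_histogram(values)
    raise ValueError(f"unknown peak-fit method {method!r}")


def _fit_peaks_em(values: np.ndarray) -> CovariancePeaks:
    from sklearn.mixture import GaussianMixture

    if values.size > _MAX_EM_SAMPLES:
        step = values.size // _MAX_EM_SAMPLES + 1
        values = values[::step]
    x = values.reshape(-1, 1)
    gmm = GaussianMixture(
        n_components=2, covariance_type="diag", n_init=5, init_params="k-means++",
        random_state=0, max_iter=300,
    )
    try:
        gmm.fit(x)
    except Exception as exc:
        raise AnalysisError(f"two-Gaussian EM failed: {exc}") from exc
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    return CovariancePeaks(
        bound_mean=float(means[order[0]]),
        bound_sd=float(sds[order[0]]),
        unbound_mean=float(means[order[1]]),
        unbound_sd=float(sds[order[1]]),
        mixture_weight=float(weights[order[0]]),
        converged=bool(gmm.converged_),
        log_likelihood=float(gmm.lower_bound_ * x.size),
    )


def _fit_peaks_histogram(values: np.ndarray) -> CovariancePeaks:
    counts, edges = np.histogram(values, bins=200, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(x, w, m1, s1, m2, s2):
        g1 = np.exp(-0.5 * ((x - m1) / s1) ** 2) / (np.abs(s1) * np.sqrt(2 * np.pi))
        g2 = np.exp(-0.5 * ((x - m2) / s2) ** 2) / (np.abs(s2) * np.sqrt(2 * np.pi))
        return w * g1 + (1 - w) * g2

    lo, hi = np.quantile(values, [0.1, 0.9])
    spread = values.std()
    last_exc: Exception | None = None
    for m1_0, m2_0 in ((lo, hi), (values.mean() - spread, values.mean() + spread)):
        try:
            popt, _ = curve_fit(
                model, centers, counts,
                p0=[0.3, m1_0, spread / 3, m2_0, spread / 3],
                bounds=([0.0, -np.inf, 1e-12, -np.inf, 1e-12], [1.0] + [np.inf] * 4),
                maxfev=20000,
            )
            break
        except Exception as exc:  # pragma: no cover - multi-start fallback
            last_exc = exc
    else:
        raise AnalysisError(f"histogram two-Gaussian fit failed: {last_exc}")
    w, m1, s1, m2, s2 = popt
    if m2 < m1:
        m1, s1, m2, s2, w = m2, s2, m1, s1, 1 - w
    return CovariancePeaks(
        bound_mean=float(m1), bound_sd=float(abs(s1)),
        unbound_mean=float(m2), unbound_sd=float(abs(s2)),
        mixture_weight=float(w),
    )


@dataclass
class StiffnessEstimate:
    """Trap stiffness via the power spectrum and via equipartition."""

    kappa_psd: float
    kappa_equipartition: float
    corner_hz: float
    ok: bool = True
    note: str = ""


def estimate_trap_stiffness(
    trace_or_x,
    *,
    bead: str = "bead_a",
    bead_radius_nm: float = physics.DEFAULT_BEAD_RADIUS_NM,
    kbt: float = physics.KBT_293K,
) -> StiffnessEstimate:
    """Trap stiffness of one bead from unbound motion.

    Fits a Lorentzian S(f) = P/(1+(f/f_c)^2) to the Welch power spectrum;
    kappa = 2*pi*gamma*f_c with Stokes drag gamma.  Cross-checked against
    equipartition kappa = kBT/var(x); both are reported.  A flat spectrum
    (no corner inside the band) is flagged as failed.
    """
    if isinstance(trace_or_x, TrapTrace):
        x = getattr(trace_or_x, bead)
        fs = trace_or_x.sample_rate
    else:
        x, fs = trace_or_x
        x = np.asarray(x, dtype=float)
    if x.size < 1e5:
        raise AnalysisError(f"stiffness estimation needs >= 1e5 samples, got {x.size}")
    gamma = physics.stokes_drag(bead_radius_nm)
    kappa_eq = kbt / x.var()

    f, pxx = welch(x - x.mean(), fs=fs, nperseg=min(x.size, 1 << 14))
    keep = f > 0
    f, pxx = f[keep], pxx[keep]
    # Flat-spectrum guard: an OU spectrum falls ~100x above the corner.
    low = pxx[f < np.quantile(f, 0.05)].mean()
    high = pxx[f > np.quantile(f, 0.8)].mean()
    if low / high < 3.0:
        return StiffnessEstimate(
            kappa_psd=float("nan"), kappa_equipartition=kappa_eq,
            corner_hz=float("nan"), ok=False,
            note="flat power spectrum: no corner frequency inside the band",
        )

    # Sampled-Lorentzian model: at finite sample rate the OU spectrum folds
    # at Nyquist, so fit the aliased AR(1) form (which reduces to the
    # Lorentzian P/(1 + (f/f_c)^2) for f_c << f_Nyquist) instead of forcing
    # the continuous curve through the folded high-frequency tail.
    def log_model(f_, log_fc, log_p):
        a = np.exp(-2.0 * np.pi * np.exp(log_fc) / fs)
        return log_p + np.log((1 - a * a) / (1 + a * a - 2 * a * np.cos(2 * np.pi * f_ / fs)))

    half = pxx[0] / 2.0
    fc0 = f[np.argmin(np.abs(pxx - half))]
    try:
        popt, _ = curve_fit(log_model, f, np.log(pxx), p0=[np.log(fc0), np.log(pxx[0])],
                            maxfev=10000)
    except Exception as exc:
        raise AnalysisError(f"Lorentzian spectrum fit failed: {exc}") from exc
    fc = float(np.exp(popt[0]))
    return StiffnessEstimate(
        kappa_psd=2.0 * np.pi * gamma * fc,
        kappa_equipartition=kappa_eq,
        corner_hz=fc,
        ok=True,
    )
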