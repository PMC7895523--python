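"""Physical constants and Ornstein-Uhlenbeck helpers for trapped-bead dynamics.

Units throughout the package: positions in nm, times in s, stiffnesses in
pN/nm, energies in pN*nm, rates in 1/s.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

#: Thermal energy k_B*T at 293 K, pN*nm.
KBT_293K = 4.045

#: Dynamic viscosity of water at 20 C, Pa*s.
WATER_VISCOSITY_20C = 1.002e-3

#: Default bead radius, nm.
DEFAULT_BEAD_RADIUS_NM = 250.0


def stokes_drag(bead_radius_nm: float, viscosity_pa_s: float = WATER_VISCOSITY_20C) -> float:
    """Stokes drag coefficient gamma = 6*pi*eta*r in pN*s/nm.

    1 N*s/m = 1e3 pN*s/nm, so gamma[pN*s/nm] = 6*pi*eta[Pa*s]*r[m]*1e3.
    """
    r_m = bead_radius_nm * 1e-9
    return 6.0 * np.pi * viscosity_pa_s * r_m * 1e3


def ou_relaxation_time(trap_stiffness: float, bead_radius_nm: float = DEFAULT_BEAD_RADIUS_NM) -> float:
    """Relaxation time tau = gamma/kappa of a bead in a harmonic trap, s."""
    return stokes_drag(bead_radius_nm) / trap_stiffness


def ou_exact_path(
    mean: np.ndarray,
    sd: np.ndarray,
    tau: float | np.ndarray,
    dt: float,
    rng: np.random.Generator,
    x0: float | None = None,
) -> np.ndarray:
    """Exactly discretized Ornstein-Uhlenbeck path with (piecewise) target mean/SD.

    The update x[n+1] = m[n] + (x[n] - m[n])*a + sd[n]*sqrt(1-a^2)*xi with
    a = exp(-dt/tau) reproduces the OU transition density exactly for any step
    size, so the stationary variance carries no discretization bias.

    Parameters
    ----------
    mean, sd : arrays of length n
        Per-sample target mean and stationary SD (change at state switches).
    tau : float or array of length n
        Relaxation time; a scalar tau allows a single O(n) recursive filter,
        a per-sample tau falls back to segment-wise filtering.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    n = mean.shape[0]
    if np.ndim(tau) == 0:
        alpha = float(np.exp(-dt / float(tau)))
        noise = sd * np.sqrt(1.0 - alpha * alpha) * rng.standard_normal(n)
        drive = (1.0 - alpha) * mean + noise
        start = rng.normal(mean[0], sd[0]) if x0 is None else float(x0)
        # x[n] = alpha*x[n-1] + drive[n]; seed the AR(1) state with x0.
        out, _ = lfilter([1.0], [1.0, -alpha], drive, zi=[alpha * start])
        return out

    tau = np.asarray(tau, dtype=float)
    # Segment-wise: constant coefficients within runs of equal tau.
    out = np.empty(n)
    boundaries = np.flatnonzero(np.diff(tau) != 0) + 1
    edges = np.concatenate(([0], boundaries, [n]))
    prev = rng.normal(mean[0], sd[0]) if x0 is None else float(x0)
    for i0, i1 in zip(edges[:-1], edges[1:]):
        alpha = float(np.exp(-dt / tau[i0]))
        seg_noise = sd[i0:i1] * np.sqrt(1.0 - alpha * alpha) * rng.standard_normal(i1 - i0)
        drive = (1.0 - alpha) * mean[i0:i1] + seg_noise
        seg, zf = lfilter([1.0], [1.0, -alpha], drive, zi=[alpha * prev])
        out[i0:i1] = seg
        prev = seg[-1]
    return out


def lorentzian_psd(f: np.ndarray, corner_hz: float, plateau: float) -> np.ndarray:
    """One-sided power spectral density of an OU process.

    S(f) = plateau / (1 + (f/f_c)^2) with plateau = 4*var*tau (nm^2/Hz) and
    corner frequency f_c = 1/(2*pi*tau) = kappa/(2*pi*gamma).
    """
    return plateau / (1.0 + (f / corner_hz) ** 2)
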