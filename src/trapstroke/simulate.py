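"""Synthetic bead-actin-bead dumbbell traces with known ground truth.

The default (phenomenological) generator decomposes the two bead positions
into a common mode c(t) and a differential mode d(t),

    bead_a = c + d/2,        bead_b = c - d/2,

each an exactly discretized Ornstein-Uhlenbeck process with relaxation time
tau_c = gamma/kappa_trap.  Myosin attachment stiffens the dumbbell, which the
generator represents by dropping the common-mode SD from sigma_c_unbound to
sigma_c_bound for the bound interval; the working stroke shifts the
common-mode target mean by d1 at attachment and by d2 more at the
substep-2 time.  Attachments arrive as a Poisson process (arrivals during a
bound interval are discarded: the three-bead geometry probes one molecule),
the dwell from attachment to substep 2 is Exponential(k2) and the dwell from
substep 2 to detachment Exponential(k3).  Sliding-window covariance of the
two beads therefore drops during bound intervals - exactly the observable the
detection stage consumes.

The mechanistic mode instead integrates the two coupled bead Langevin
equations with stiffness matrix (traps + inter-bead link), where binding adds
kappa_m/4 to every matrix element through a myosin spring anchored at the
bead midpoint; the anchor is shifted by d*(1 + 2*kappa_trap/kappa_m) so the
expected bead displacement equals d after series-spring attenuation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import physics
from .errors import ConfigurationError
from .trace import TrapTrace, write_trace_tsv


@dataclass
class SimulationConfig:
    """Parameters of one simulated dumbbell recording.

    Rates are 1/s, lengths nm, stiffnesses pN/nm, times s.
    """

    sample_rate: float = 25_000.0
    duration: float = 20.0
    seed: int = 0
    temperature: float = 293.0
    trap_stiffness: float = 0.06       # per bead, mid-range of typical 0.05-0.07
    bead_radius: float = physics.DEFAULT_BEAD_RADIUS_NM
    common_mode_relax_time: float | None = None   # default gamma/kappa_trap
    unbound_common_sd: float = 5.8    # sqrt(kBT/(2*kappa_trap)): equipartition, unbound
    bound_common_sd: float = 1.9      # sqrt(kBT/(2*kappa_trap + kappa_m)) with kappa_m ~ 1 pN/nm
    differential_sd: float = 4.0
    attach_rate: float = 1.0
    substep1: float = 3.32
    substep2: float = 1.09             # 0 selects single-step mode
    substep2_rate: float = 99.1
    detach_rate: float = 4.59
    slow_population_fraction: float = 0.0
    slow_detach_rate: float = 1.0
    mode: str = "phenomenological"     # or "mechanistic"
    myosin_stiffness: float = 1.0      # kappa_m, mechanistic mode only
    link_stiffness: float = 0.1        # actin tether between beads, mechanistic mode
    molecule_id: str = "sim-0"
    condition: str = ""

    def __post_init__(self) -> None:
        if self.common_mode_relax_time is None:
            self.common_mode_relax_time = physics.stokes_drag(self.bead_radius) / self.trap_stiffness
        self.validate()

    def validate(self) -> None:
        positives = {
            "sample_rate": self.sample_rate,
            "duration": self.duration,
            "temperature": self.temperature,
            "trap_stiffness": self.trap_stiffness,
            "bead_radius": self.bead_radius,
            "common_mode_relax_time": self.common_mode_relax_time,
        }
        for name, value in positives.items():
            if not np.isfinite(value) or value <= 0:
                raise ConfigurationError(f"{name} must be finite and positive, got {value}")
        nonneg = {
            "unbound_common_sd": self.unbound_common_sd,
            "bound_common_sd": self.bound_common_sd,
            "differential_sd": self.differential_sd,
            "attach_rate": self.attach_rate,
            "substep2_rate": self.substep2_rate,
            "detach_rate": self.detach_rate,
            "slow_detach_rate": self.slow_detach_rate,
            "myosin_stiffness": self.myosin_stiffness,
            "link_stiffness": self.link_stiffness,
        }
        for name, value in nonneg.items():
            if not np.isfinite(value) or value < 0:
                raise ConfigurationError(f"{name} must be finite and non-negative, got {value}")
        if not np.isfinite(self.substep1) or not np.isfinite(self.substep2):
            raise ConfigurationError("substep amplitudes must be finite")
        if not 0.0 <= self.slow_population_fraction <= 1.0:
            raise ConfigurationError("slow_population_fraction must lie in [0, 1]")
        if self.mode not in ("phenomenological", "mechanistic"):
            raise ConfigurationError(f"unknown simulation mode {self.mode!r}")

    @property
    def single_step(self) -> bool:
        return self.substep2 == 0.0

    @property
    def kbt(self) -> float:
        return physics.KBT_293K * self.temperature / 293.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruthEvent:
    """One true attachment interval with the applied working-stroke shifts."""

    attach_time: float
    detach_time: float
    substep2_time: float | None = None
    applied_shift_1: float = 0.0
    applied_shift_2: float = 0.0

    @property
    def duration(self) -> float:
        return self.detach_time - self.attach_time


def _draw_events(config: SimulationConfig, rng: np.random.Generator) -> list[GroundTruthEvent]:
    events: list[GroundTruthEvent] = []
    if config.attach_rate == 0:
        return events
    t = 0.0
    while True:
        # First Poisson arrival after the previous detachment (arrivals inside
        # bound intervals are discarded; memorylessness collapses them to one draw).
        t = t + rng.exponential(1.0 / config.attach_rate)
        if config.slow_population_fraction > 0 and rng.random() < config.slow_population_fraction:
            k_det = config.slow_detach_rate
        else:
            k_det = config.detach_rate
        if config.single_step:
            sub = None
            detach = t + rng.exponential(1.0 / k_det)
        else:
            sub = t + rng.exponential(1.0 / config.substep2_rate)
            detach = sub + rng.exponential(1.0 / k_det)
        if detach >= config.duration:
            break
        events.append(
            GroundTruthEvent(
                attach_time=t,
                detach_time=detach,
                substep2_time=sub,
                applied_shift_1=config.substep1,
                applied_shift_2=0.0 if config.single_step else config.substep2,
            )
        )
        t = detach
    return events


def _state_arrays(config: SimulationConfig, events: list[GroundTruthEvent], n: int):
    """Per-sample bound mask and common-mode target mean from the event list."""
    dt = 1.0 / config.sample_rate
    bound = np.zeros(n, dtype=bool)
    mean_c = np.zeros(n)
    for ev in events:
        i0 = int(np.ceil(ev.attach_time / dt))
        i1 = min(n, int(np.ceil(ev.detach_time / dt)))
        bound[i0:i1] = True
        if ev.substep2_time is None:
            mean_c[i0:i1] += ev.applied_shift_1
        else:
            im = min(i1, int(np.ceil(ev.substep2_time / dt)))
            mean_c[i0:im] += ev.applied_shift_1
            mean_c[im:i1] += ev.applied_shift_1 + ev.applied_shift_2
    return bound, mean_c


def _simulate_phenomenological(config, events, rng) -> TrapTrace:
    n = int(round(config.duration * config.sample_rate))
    dt = 1.0 / config.sample_rate
    bound, mean_c = _state_arrays(config, events, n)
    sd_c = np.where(bound, config.bound_common_sd, config.unbound_common_sd)
    c = physics.ou_exact_path(mean_c, sd_c, config.common_mode_relax_time, dt, rng)
    d = physics.ou_exact_path(
        np.zeros(n), np.full(n, config.differential_sd), config.common_mode_relax_time, dt, rng
    )
    return TrapTrace(
        sample_interval=dt,
        bead_a=c + 0.5 * d,
        bead_b=c - 0.5 * d,
        trap_stiffness_a=config.trap_stiffness,
        trap_stiffness_b=config.trap_stiffness,
        molecule_id=config.molecule_id,
        condition=config.condition,
        source="simulated",
        seed=config.seed,
    )


def stiffness_matrix(config: SimulationConfig, bound: bool) -> np.ndarray:
    """2x2 stiffness matrix of the dumbbell (mechanistic mode).

    Unbound: traps on the diagonal plus the inter-bead link; binding adds
    kappa_m/4 to every element (midpoint-anchored myosin spring).
    """
    kt, kl = config.trap_stiffness, config.link_stiffness
    K = np.array([[kt + kl, -kl], [-kl, kt + kl]])
    if bound:
        K = K + config.myosin_stiffness / 4.0
    return K


def _simulate_mechanistic(config, events, rng) -> TrapTrace:
    # Normal modes of the symmetric 2x2 system: y1 = (x_a+x_b)/sqrt(2) with
    # eigenvalue kt (+ kappa_m/2 bound), y2 = (x_a-x_b)/sqrt(2) with
    # eigenvalue kt + 2*kl (binding leaves it untouched). Each mode is an OU
    # process with rate eig/gamma and stationary variance kBT/eig.
    n = int(round(config.duration * config.sample_rate))
    dt = 1.0 / config.sample_rate
    gamma = physics.stokes_drag(config.bead_radius)
    kbt = config.kbt
    kt, km = config.trap_stiffness, config.myosin_stiffness

    bound, mean_c = _state_arrays(config, events, n)
    # Anchor calibration: a shift d of the anchor by d*(1+2kt/km) yields a mean
    # midpoint displacement of exactly d after series-spring attenuation.
    anchor = mean_c * (1.0 + 2.0 * kt / km)
    mean_s = np.where(bound, anchor * km / (2.0 * kt + km), 0.0)

    eig1 = np.where(bound, kt + km / 2.0, kt)      # common mode, per bead pair
    tau1 = gamma / eig1
    sd1 = np.sqrt(kbt / (2.0 * eig1)) * np.sqrt(2.0)   # y1 = sqrt(2)*s, var(s)=kBT/(2*eig1)
    mean_y1 = np.sqrt(2.0) * mean_s
    y1 = physics.ou_exact_path(mean_y1, sd1, tau1, dt, rng)

    eig2 = kt + 2.0 * config.link_stiffness
    sd2 = np.full(n, np.sqrt(kbt / eig2))
    y2 = physics.ou_exact_path(np.zeros(n), sd2, gamma / eig2, dt, rng)

    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    return TrapTrace(
        sample_interval=dt,
        bead_a=(y1 + y2) * inv_sqrt2,
        bead_b=(y1 - y2) * inv_sqrt2,
        trap_stiffness_a=kt,
        trap_stiffness_b=kt,
        molecule_id=config.molecule_id,
        condition=config.condition,
        source="simulated",
        seed=config.seed,
    )


def simulate_dumbbell(config: SimulationConfig) -> tuple[TrapTrace, list[GroundTruthEvent]]:
    """Simulate a dumbbell recording; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    events = _draw_events(config, rng)
    if config.mode == "mechanistic":
        trace = _simulate_mechanistic(config, events, rng)
    else:
        trace = _simulate_phenomenological(config, events, rng)
    return trace, events


def duration_for_events(config: SimulationConfig, n_events: int, margin: float = 1.25) -> float:
    """Trace duration expected to contain about ``n_events`` attachments."""
    mean_cycle = 1.0 / config.attach_rate + 1.0 / config.detach_rate
    if not config.single_step:
        mean_cycle += 1.0 / config.substep2_rate
    return n_events * mean_cycle * margin


def sample_durations(
    rates: list[float] | np.ndarray,
    amplitudes: list[float] | np.ndarray,
    n: int,
    dead_time: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw attachment durations from an exponential mixture conditioned on
    exceeding the instrument dead time (draw-and-reject)."""
    rates = np.asarray(rates, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if rates.size == 0:
        raise ConfigurationError("rates must be non-empty")
    if rates.shape != amplitudes.shape:
        raise ConfigurationError("rates and amplitudes must have equal length")
    if np.any(rates <= 0):
        raise ConfigurationError("all rates must be positive")
    if abs(amplitudes.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"amplitudes must sum to 1, got {amplitudes.sum()}")
    if n <= 0:
        raise ConfigurationError("n must be positive")
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = 2 * (n - filled) + 16
        comp = rng.choice(rates.size, size=m, p=amplitudes)
        draws = rng.exponential(1.0 / rates[comp])
        keep = draws[draws >= dead_time]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


# --- Condition presets --------------------------------------------------
# Working-stroke amplitudes (nm) and ensemble rates (1/s) for the conditions
# the analysis is benchmarked against: wild-type beta-cardiac HMM, the R712L
# converter mutant (single-step stroke), and R712L rescued by omecamtiv
# mecarbil.  Detachment-rate mixtures are the saturating-ATP dwell fits.

ENSEMBLE_PRESETS: dict[str, dict] = {
    "wt": dict(substep1=3.32, substep2=1.09, substep2_rate=99.1, detach_rate=4.59,
               condition="WT, 1 uM ATP"),
    "r712l": dict(substep1=1.29, substep2=0.0, substep2_rate=0.0, detach_rate=7.56,
                  condition="R712L, 1 uM ATP"),
    "r712l_om50": dict(substep1=1.82, substep2=0.84, substep2_rate=39.8, detach_rate=9.61,
                       condition="R712L + 50 uM OM, 1 uM ATP"),
    "r712l_om200": dict(substep1=2.28, substep2=1.14, substep2_rate=41.8, detach_rate=6.29,
                        condition="R712L + 200 uM OM, 1 uM ATP"),
}

DWELL_PRESETS: dict[str, dict] = {
    "wt_1um": dict(rates=[6.89], amplitudes=[1.0]),
    "wt_1mm": dict(rates=[54.4, 7.5], amplitudes=[0.97, 0.03]),
    "r712l_1um": dict(rates=[7.56], amplitudes=[1.0]),
    "r712l_1mm": dict(rates=[69.7, 7.4], amplitudes=[0.91, 0.09]),
    "r712l_om50_1mm": dict(rates=[63.8, 6.0], amplitudes=[0.94, 0.06]),
}


def preset_config(name: str, **overrides) -> SimulationConfig:
    """A SimulationConfig parameterized from a named condition preset."""
    if name not in ENSEMBLE_PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(ENSEMBLE_PRESETS)}")
    params = dict(ENSEMBLE_PRESETS[name])
    params.setdefault("molecule_id", f"{name}-sim")
    params.update(overrides)
    if params.get("substep2_rate", 1.0) == 0.0:
        params["substep2_rate"] = 1.0  # unused in single-step mode, keep valid
    return SimulationConfig(**params)


def make_fixture_suite(out_dir: str | Path, seed: int = 0, trace_duration: float = 20.0) -> dict:
    """Write named trace + ground-truth fixtures and a parameter manifest.

    Produces a two-substep wild-type-like trace, a single-step R712L-like
    trace, an OM-rescue trace, and fast/slow two-population dwell samples.
    Byte-identical for identical seeds.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigurationError(f"cannot create fixture directory {out_dir}: {exc}") from exc
    rng = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in rng.generate_state(4) % (2**31)]
    manifest: dict = {"seed": seed, "fixtures": {}}
    for (name, child) in zip(("wt", "r712l", "r712l_om200"), child_seeds):
        config = preset_config(name, seed=child, duration=trace_duration)
        trace, truth = simulate_dumbbell(config)
        trace_path = out_dir / f"{name}_trace.tsv"
        truth_path = out_dir / f"{name}_truth.csv"
        write_trace_tsv(trace, trace_path)
        write_ground_truth_csv(truth, truth_path)
        manifest["fixtures"][name] = {
            "trace": trace_path.name,
            "truth": truth_path.name,
            "n_events": len(truth),
            "parameters": config.to_dict(),
        }
    dwell_name = "wt_1mm"
    params = DWELL_PRESETS[dwell_name]
    durations = sample_durations(
        params["rates"], params["amplitudes"], n=2000, dead_time=0.015, seed=child_seeds[3]
    )
    dwell_path = out_dir / f"{dwell_name}_durations.csv"
    np.savetxt(dwell_path, durations, fmt="%.8f", header="duration_s", comments="")
    manifest["fixtures"][dwell_name] = {
        "durations": dwell_path.name,
        "n": 2000,
        "dead_time_s": 0.015,
        "parameters": params,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_ground_truth_csv(events: list[GroundTruthEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("event_index,attach_time_s,substep2_time_s,detach_time_s,shift1_nm,shift2_nm\n")
        for i, ev in enumerate(events):
            sub = "" if ev.substep2_time is None else f"{ev.substep2_time:.8f}"
            fh.write(
                f"{i},{ev.attach_time:.8f},{sub},{ev.detach_time:.8f},"
                f"{ev.applied_shift_1:.4f},{ev.applied_shift_2:.4f}\n"
            )


def read_ground_truth_csv(path: str | Path) -> list[GroundTruthEvent]:
    import pandas as pd

    table = pd.read_csv(path)
    events = []
    for _, row in table.iterrows():
        sub = row["substep2_time_s"]
        events.append(
            GroundTruthEvent(
                attach_time=float(row["attach_time_s"]),
                detach_time=float(row["detach_time_s"]),
                substep2_time=None if pd.isna(sub) else float(sub),
                applied_shift_1=float(row["shift1_nm"]),
                applied_shift_2=float(row["shift2_nm"]),
            )
        )
    return events
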