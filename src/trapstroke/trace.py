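"""The two-bead position record and its on-disk formats.

The canonical interchange format is a TSV with a single '#'-prefixed JSON
metadata line followed by ``time_s  bead_a_nm  bead_b_nm`` columns; an HDF5
container with the same schema is provided for long recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

_REQUIRED_META = (
    "sample_rate_hz",
    "trap_stiffness_a_pn_per_nm",
    "trap_stiffness_b_pn_per_nm",
    "molecule_id",
    "condition",
    "source",
)


@dataclass
class TrapTrace:
    """Synchronized position records of the two dumbbell beads.

    Attributes
    ----------
    sample_interval : s between samples (inverse acquisition rate).
    bead_a, bead_b : nm position series, equal length >= 2.
    trap_stiffness_a, trap_stiffness_b : pN/nm, from calibration.
    molecule_id : identifier of the pedestal-bead molecule probed.
    condition : free-text solution condition (ATP / drug concentrations).
    source : 'simulated' or 'imported'.
    seed : generator seed when simulated (None for imported data).
    """

    sample_interval: float
    bead_a: np.ndarray
    bead_b: np.ndarray
    trap_stiffness_a: float = 0.06
    trap_stiffness_b: float = 0.06
    molecule_id: str = "molecule-0"
    condition: str = ""
    source: str = "simulated"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.bead_a = np.asarray(self.bead_a, dtype=float)
        self.bead_b = np.asarray(self.bead_b, dtype=float)
        if self.sample_interval <= 0:
            raise FormatError("sample_interval must be positive")
        if self.bead_a.shape != self.bead_b.shape or self.bead_a.ndim != 1:
            raise FormatError("bead_a and bead_b must be 1-D arrays of equal length")
        if self.bead_a.size < 2:
            raise FormatError("trace must contain at least 2 samples")
        if not (np.isfinite(self.bead_a).all() and np.isfinite(self.bead_b).all()):
            raise FormatError("bead positions must be finite")

    @property
    def n_samples(self) -> int:
        return self.bead_a.size

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.sample_interval

    @property
    def duration(self) -> float:
        return self.n_samples * self.sample_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval

    def displacement(self, signal: str = "mean", sign: float = 1.0) -> np.ndarray:
        """Displacement series used for ensemble averaging.

        ``signal`` is 'mean' (average of the two beads; halves uncorrelated
        noise), 'bead_a' or 'bead_b'. ``sign`` of -1 flips the convention.
        """
        if signal == "mean":
            out = 0.5 * (self.bead_a + self.bead_b)
        elif signal == "bead_a":
            out = self.bead_a
        elif signal == "bead_b":
            out = self.bead_b
        else:
            raise ValueError(f"unknown displacement signal {signal!r}")
        return sign * out

    def segment(self, t_start: float, t_end: float, condition: str | None = None) -> "TrapTrace":
        """View of the trace restricted to [t_start, t_end)."""
        i0 = max(0, int(np.ceil(t_start / self.sample_interval)))
        i1 = min(self.n_samples, int(np.floor(t_end / self.sample_interval)))
        return replace(
            self,
            bead_a=self.bead_a[i0:i1],
            bead_b=self.bead_b[i0:i1],
            condition=self.condition if condition is None else condition,
        )

    def _metadata(self) -> dict:
        meta = {
            "sample_rate_hz": self.sample_rate,
            "trap_stiffness_a_pn_per_nm": self.trap_stiffness_a,
            "trap_stiffness_b_pn_per_nm": self.trap_stiffness_b,
            "molecule_id": self.molecule_id,
            "condition": self.condition,
            "source": self.source,
        }
        if self.seed is not None:
            meta["seed"] = self.seed
        return meta


def write_trace_tsv(trace: TrapTrace, path: str | Path) -> None:
    """Write a trace as TSV with a '#'-prefixed JSON metadata header.

    Positions are printed to 1e-4 nm, far below instrument noise.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(trace._metadata(), sort_keys=True) + "\n")
        fh.write("time_s\tbead_a_nm\tbead_b_nm\n")
        t = trace.times
        for i in range(trace.n_samples):
            fh.write(f"{t[i]:.8f}\t{trace.bead_a[i]:.4f}\t{trace.bead_b[i]:.4f}\n")


def read_trace_tsv(path: str | Path) -> TrapTrace:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: line 1: expected '#'-prefixed JSON metadata header")
        try:
            meta = json.loads(header.lstrip("#").strip())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: line 1: invalid JSON metadata: {exc}") from exc
        for key in _REQUIRED_META:
            if key not in meta:
                raise FormatError(f"{path}: metadata missing required key '{key}'")
        try:
            table = pd.read_csv(fh, sep="\t")
        except Exception as exc:  # ragged rows, bad numbers
            raise FormatError(f"{path}: could not parse data columns: {exc}") from exc
    for col in ("time_s", "bead_a_nm", "bead_b_nm"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    if table[["time_s", "bead_a_nm", "bead_b_nm"]].isna().any().any():
        bad = int(table[["time_s", "bead_a_nm", "bead_b_nm"]].isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: line {bad + 3}: ragged or non-numeric row")
    t = table["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0))
        raise FormatError(f"{path}: line {bad + 4}: non-monotone time column")
    return TrapTrace(
        sample_interval=1.0 / float(meta["sample_rate_hz"]),
        bead_a=table["bead_a_nm"].to_numpy(),
        bead_b=table["bead_b_nm"].to_numpy(),
        trap_stiffness_a=float(meta["trap_stiffness_a_pn_per_nm"]),
        trap_stiffness_b=float(meta["trap_stiffness_b_pn_per_nm"]),
        molecule_id=str(meta["molecule_id"]),
        condition=str(meta["condition"]),
        source=str(meta["source"]),
        seed=meta.get("seed"),
    )


def write_trace_hdf5(trace: TrapTrace, path: str | Path) -> None:
    """Bit-exact HDF5 container with the TSV schema as datasets + attrs."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("bead_a_nm", data=trace.bead_a)
        h5.create_dataset("bead_b_nm", data=trace.bead_b)
        for key, value in trace._metadata().items():
            h5.attrs[key] = value


def read_trace_hdf5(path: str | Path) -> TrapTrace:
    import h5py

    with h5py.File(path, "r") as h5:
        meta = dict(h5.attrs)
        for key in _REQUIRED_META:
            if key not in meta:
                raise FormatError(f"{path}: metadata missing required key '{key}'")
        return TrapTrace(
            sample_interval=1.0 / float(meta["sample_rate_hz"]),
            bead_a=h5["bead_a_nm"][:],
            bead_b=h5["bead_b_nm"][:],
            trap_stiffness_a=float(meta["trap_stiffness_a_pn_per_nm"]),
            trap_stiffness_b=float(meta["trap_stiffness_b_pn_per_nm"]),
            molecule_id=str(meta["molecule_id"]),
            condition=str(meta["condition"]),
            source=str(meta["source"]),
            seed=int(meta["seed"]) if "seed" in meta else None,
        )


def read_trace(path: str | Path) -> TrapTrace:
    """Dispatch on extension: .h5/.hdf5 -> HDF5 container, else TSV."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return read_trace_hdf5(path)
    return read_trace_tsv(path)


def write_trace(trace: TrapTrace, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        write_trace_hdf5(trace, path)
    else:
        write_trace_tsv(trace, path)
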