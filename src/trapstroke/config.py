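"""Pipeline configuration: every analysis knob in one schema-versioned
record, so that the config echo in a run report reproduces the run exactly."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Defaults reproduce the published analysis settings: 30 ms covariance
    window, halfway/80% refinement thresholds, 0.75-dead-time boundary
    shifts, and the >75-events molecule inclusion rule."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    covariance_window_ms: float = 30.0
    auto_window_search: bool = False           # optional search over candidates
    window_candidates_ms: tuple = (20.0, 25.0, 30.0)
    peak_fit_method: str = "em"                # 'em' | 'histogram'
    start_threshold_fraction: float = 0.5
    end_threshold_fraction: float = 0.8
    shift_fraction_of_dead_time: float = 0.75
    near_window_factor: float = 1.5
    min_duration_dead_times: float = 1.0
    min_events_per_molecule: int = 76
    extension_span_s: float = 0.5
    pad_s: float = 0.25
    displacement_signal: str = "mean"          # 'mean' | 'bead_a' | 'bead_b'
    displacement_sign: float = 1.0
    resolution_floor_nm: float = 0.2
    forward_fit_start_dead_times: float = 1.0
    reverse_fit_start_dead_times: float = 1.6
    forward_fit_window_s: float | None = 0.3    # substep-2 rises are fast
    reverse_fit_window_s: float | None = None   # detachment rises span the whole extension
    mle_max_order: int = 2
    mle_n_starts: int = 20
    model_selection_alpha: float = 0.05
    n_boot: int = 1000
    run_bootstrap: bool = False

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigurationError(
                f"unsupported config schema_version {self.schema_version} "
                f"(this version reads {SCHEMA_VERSION})"
            )
        if self.covariance_window_ms <= 0:
            raise ConfigurationError("covariance_window_ms must be positive")
        if not 0 < self.start_threshold_fraction < 1:
            raise ConfigurationError("start_threshold_fraction must lie in (0, 1)")
        if not 0 < self.end_threshold_fraction <= 1:
            raise ConfigurationError("end_threshold_fraction must lie in (0, 1]")
        if self.displacement_signal not in ("mean", "bead_a", "bead_b"):
            raise ConfigurationError(f"unknown displacement_signal {self.displacement_signal!r}")

    @property
    def covariance_window_s(self) -> float:
        return self.covariance_window_ms * 1e-3

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["window_candidates_ms"] = list(self.window_candidates_ms)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "window_candidates_ms" in data:
            data = dict(data, window_candidates_ms=tuple(data["window_candidates_ms"]))
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
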