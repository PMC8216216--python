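"""Run configuration: schema-validated settings for simulation and analysis.

A run config is a JSON file with up to four sections::

    {
      "device":   { "tube_volume": 2.6, ... },       # DeviceConfig fields
      "sample":   { "psi50_true": -3.0, ... },       # SampleModel fields
      "analysis": { "t_i": 2.0, "t_f": 15.0, ... },  # AnalysisConfig fields
      "seed": 0,
      "duration_hours": 10.0
    }

Unknown or missing required fields raise :class:`ConfigError` naming
the field, before anything runs.  Every default traces back either to
the instrument's documented behaviour or to an explicit design choice
in the methods note.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError
from .synthetic_device import DeviceConfig, SampleModel

__all__ = ["AnalysisConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of the log-to-curve analysis chain.

    ``t_i``/``t_f`` are the endpoint times (s) within each cycle
    (defaults skip the pump transient and use the recommended 15 s
    extraction endpoint); ``window`` the half-width (s) of the
    endpoint averaging windows.  Grid/matching/plateau parameters are
    documented on the functions they feed.
    """

    t_i: float = 2.0
    t_f: float = 15.0
    window: float = 0.5
    grid_interval: float = 15.0       # min
    match_tolerance: float = 7.5      # min
    gdmin_cycles: int = 3
    plateau_tol: float = 0.05
    plateau_min_cycles: int = 4
    start_tolerance: float = 5.0      # kPa, p_i sanity band around vacuum target

    def __post_init__(self) -> None:
        if not (0 <= self.t_i < self.t_f):
            raise ConfigError("require 0 <= t_i < t_f")
        if self.t_i + self.window >= self.t_f - self.window:
            raise ConfigError("endpoint windows overlap: t_i + window >= t_f - window")
        if self.grid_interval <= 0 or self.match_tolerance <= 0:
            raise ConfigError("grid_interval and match_tolerance must be positive")


@dataclass(frozen=True)
class RunConfig:
    device: DeviceConfig
    sample: SampleModel
    analysis: AnalysisConfig
    seed: int = 0
    duration_hours: float = 10.0

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build(cls, section: str, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ConfigError(f"unknown field(s) {unknown} in section '{section}'")
    required = [n for n, f in fields.items()
                if f.default is dataclasses.MISSING
                and f.default_factory is dataclasses.MISSING]
    missing = sorted(set(required) - set(data))
    if missing:
        raise ConfigError(f"missing required field(s) {missing} in section '{section}'")
    if cls is SampleModel and "psi_schedule" in data:
        data = dict(data)
        data["psi_schedule"] = tuple(tuple(p) for p in data["psi_schedule"])
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config file {path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a JSON object")
    known = {"device", "sample", "analysis", "seed", "duration_hours"}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {unknown}; expected {sorted(known)}")
    if "device" not in raw:
        raise ConfigError("config must contain a 'device' section")
    device = _build(DeviceConfig, "device", raw["device"])
    sample = _build(SampleModel, "sample", raw.get("sample", {}))
    analysis = _build(AnalysisConfig, "analysis", raw.get("analysis", {}))
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("'seed' must be an integer")
    duration = raw.get("duration_hours", 10.0)
    if not isinstance(duration, (int, float)) or duration <= 0:
        raise ConfigError("'duration_hours' must be a positive number")
    return RunConfig(device=device, sample=sample, analysis=analysis,
                     seed=seed, duration_hours=float(duration))
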