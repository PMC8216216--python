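"""Core in-memory records for one measurement cycle.

A cycle is one automated gas extraction: the pump pulls the discharge
tube down to a partial vacuum (~40 kPa absolute), the pressure is logged
while gas diffuses in from the sample, and the tube is vented.  The
analysis only ever needs two numbers per cycle — the pressure at the
initial and final endpoint times — plus quality flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

__all__ = ["PressureTrace", "MeasurementCycle"]


@dataclass
class PressureTrace:
    """Timestamped absolute-pressure series of a single extraction phase.

    Attributes
    ----------
    measurement_id : int
        Cycle counter, increments once per cycle in the log.
    start_datetime : datetime
        Wall-clock time of the first sample.
    times : ndarray
        Seconds since cycle start, strictly increasing.
    pressures : ndarray
        Absolute pressure in kPa; finite and in (0, 120].
    pump_events : ndarray of int
        Sample indices at which the vacuum pump restarted (the pressure
        reached the restart threshold and the tube was re-evacuated).
    """

    measurement_id: int
    start_datetime: datetime
    times: np.ndarray
    pressures: np.ndarray
    pump_events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.pump_events = np.asarray(self.pump_events, dtype=int)
        if self.times.shape != self.pressures.shape:
            raise ValueError("times and pressures must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.pressures)):
            raise ValueError("pressures must be finite")
        if self.pressures.size and (
            np.any(self.pressures <= 0) or np.any(self.pressures > 120.0)
        ):
            raise ValueError("pressures must lie in (0, 120] kPa")

    @property
    def duration(self) -> float:
        """Length of the trace in seconds."""
        return float(self.times[-1]) if self.times.size else 0.0


@dataclass
class MeasurementCycle:
    """Endpoint summary of one cycle: p_i, p_f and quality flags.

    ``delta_p = p_f - p_i`` is the pressure rise driving the ideal-gas
    discharge computation.  A cycle is excluded from gas-discharge
    series when any flag is set: a mid-interval pump restart re-evacuates
    the reservoir (invalidating the interval), truncation means the log
    ended before the final endpoint, and an out-of-range initial
    pressure indicates the pump never reached its vacuum target.
    """

    measurement_id: int
    start_datetime: datetime
    p_i: float
    p_f: float
    pump_restart: bool = False
    truncated: bool = False
    endpoint_out_of_range: bool = False

    @property
    def delta_p(self) -> float:
        """Pressure rise p_f - p_i in kPa."""
        return self.p_f - self.p_i

    @property
    def ok(self) -> bool:
        """True when no quality flag is set."""
        return not (self.pump_restart or self.truncated or self.endpoint_out_of_range)

    @property
    def flags(self) -> dict:
        return {
            "pump_restart": self.pump_restart,
            "truncated": self.truncated,
            "endpoint_out_of_range": self.endpoint_out_of_range,
        }
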