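"""Physical computations: ideal-gas discharge, calibration, tube sizing, leaks.

The pneumatic method quantifies embolism through the amount of gas that
diffuses from the sample into a partially evacuated reservoir of known
volume.  With the tube volume V_t fixed and temperature constant, the
ideal gas law converts the per-cycle pressure rise into moles,

    n = delta_p * V_t / (R * T),

conventionally re-expressed as the equivalent gas volume at atmospheric
pressure (µL), which is the unit vulnerability curves are built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FlaggedCycleError, InsufficientDataError
from .records import MeasurementCycle

__all__ = [
    "GasDischarge",
    "CalibrationFit",
    "CalibrationSetup",
    "LeakVerdict",
    "gas_discharge",
    "gas_discharge_series",
    "water_column_pressure",
    "syringe_pressure",
    "fit_calibration",
    "size_discharge_tube",
    "leak_check",
    "TUBE_SIZING_DIVISOR",
    "GAS_CONSTANT",
]

GAS_CONSTANT = 8.3145  # J mol^-1 K^-1

#: empirical divisor: ideal tube volume (mL) = max gas discharged (uL) / 510.2
TUBE_SIZING_DIVISOR = 510.2


@dataclass(frozen=True)
class GasDischarge:
    """Gas extracted in one cycle, as moles and as µL at atmospheric pressure."""

    measurement_id: int
    datetime: datetime
    moles: float
    ul_atm: float


@dataclass(frozen=True)
class CalibrationFit:
    """Linear sensor calibration: pressure (kPa) = slope * voltage + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class CalibrationSetup:
    """Water-column calibration constants: P = rho * g * h (Pa)."""

    rho: float = 1000.0  # kg m^-3, water
    g: float = 9.81      # m s^-2
    heights: tuple = ()

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.heights):
            raise ValueError("column heights must be >= 0 m")


@dataclass(frozen=True)
class LeakVerdict:
    """Outcome of a blocked-tube leak test."""

    status: str  # tight | suspicious | leaking
    max_drift_pct: float
    monotone_decreasing: bool
    n_cycles: int


def gas_discharge(
    cycle: MeasurementCycle,
    tube_volume: float,
    temperature: float = 293.15,
    atm_pressure: float = 101.3,
    gas_constant: float = GAS_CONSTANT,
) -> GasDischarge:
    """Ideal-gas-law discharge for one unflagged cycle.

    ``moles = delta_p * V_t / (R T)`` in SI, and the atmospheric-
    equivalent volume ``delta_p * V_t / P_atm`` in µL (pressures cancel
    unit-wise, so kPa and mL can be used directly there).
    """
    if tube_volume <= 0:
        raise ValueError("tube_volume must be positive (mL)")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    if not cycle.ok:
        raise FlaggedCycleError(
            f"cycle {cycle.measurement_id} is flagged "
            f"({ {k: v for k, v in cycle.flags.items() if v} }); "
            "flagged cycles carry no valid extraction interval"
        )
    delta_p_pa = cycle.delta_p * 1e3
    v_t_m3 = tube_volume * 1e-6
    moles = delta_p_pa * v_t_m3 / (gas_constant * temperature)
    ul_atm = cycle.delta_p * tube_volume / atm_pressure * 1000.0
    return GasDischarge(cycle.measurement_id, cycle.start_datetime, moles, ul_atm)


def gas_discharge_series(
    cycles: Sequence[MeasurementCycle],
    tube_volume: float,
    temperature: float = 293.15,
    atm_pressure: float = 101.3,
) -> tuple[pd.DataFrame, int]:
    """Per-cycle discharge table for the unflagged cycles.

    Returns the frame (measurement_id, datetime, moles, ul_atm) and the
    number of flagged cycles excluded.
    """
    rows, n_excluded = [], 0
    for c in cycles:
        if not c.ok:
            n_excluded += 1
            continue
        gd = gas_discharge(c, tube_volume, temperature, atm_pressure)
        rows.append((gd.measurement_id, gd.datetime, gd.moles, gd.ul_atm))
    frame = pd.DataFrame(rows, columns=["measurement_id", "datetime", "moles", "ul_atm"])
    return frame, n_excluded


def water_column_pressure(setup: CalibrationSetup, h: float) -> float:
    """Hydrostatic pressure (Pa) of a water column of height ``h`` metres."""
    if h < 0:
        raise ValueError("column height must be >= 0 m")
    return setup.rho * setup.g * h


def syringe_pressure(v0: float, v: float, atm_pressure: float = 101.3) -> float:
    """Relative pressure (kPa) after isothermal compression of a syringe.

    Boyle's law for air sealed at ambient pressure in a syringe of
    volume ``v0`` compressed to ``v``: absolute pressure is
    ``P_atm * v0 / v``, reported relative to ambient.  The instrument's
    syringe calibration uses a 60 mL syringe; at sea-level round
    numbers (100 kPa) compressing to 50/40/30 mL gives 20/50/100 kPa.
    """
    if v <= 0:
        raise ValueError("compressed volume must be positive")
    if v > v0:
        raise ValueError("compressed volume cannot exceed the starting volume")
    return atm_pressure * (v0 / v - 1.0)


def fit_calibration(voltages: Sequence[float], pressures: Sequence[float]) -> CalibrationFit:
    """Ordinary least squares of applied pressure (kPa) on sensor voltage.

    The slope and intercept are what gets programmed into the device so
    it reports kPa instead of raw sensor output.
    """
    v = np.asarray(voltages, dtype=float)
    p = np.asarray(pressures, dtype=float)
    if v.size != p.size:
        raise ValueError("voltages and pressures must have equal length")
    if v.size < 2:
        raise InsufficientDataError("calibration needs at least 2 points")
    if np.unique(v).size < 2:
        raise InsufficientDataError(
            "all voltages identical: cannot fit a calibration line")
    res = stats.linregress(v, p)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(v.size),
    )


def size_discharge_tube(gd_max: float) -> float:
    """Recommended discharge-tube volume (mL) for a given maximum discharge.

    Empirical precision optimum: tube volume = GDmax (µL) / 510.2.
    """
    if gd_max <= 0:
        raise ValueError("gd_max must be positive (uL)")
    return gd_max / TUBE_SIZING_DIVISOR


def leak_check(
    series: Sequence[float],
    tight_drift_pct: float = 2.0,
    leak_drift_pct: float = 5.0,
    decreasing_step_fraction: float = 0.8,
) -> LeakVerdict:
    """Judge a blocked-tube (sealed) run for leakage.

    The first cycle is dropped (it is close to zero while the tube
    first equilibrates).  Drift is the relative range
    ``(max - min) / max * 100`` over the retained cycles.  The verdict
    is ``leaking`` when drift exceeds ``leak_drift_pct`` AND the series
    decreases regularly (at least ``decreasing_step_fraction`` of
    consecutive steps negative), ``tight`` when drift stays within
    ``tight_drift_pct``, and ``suspicious`` otherwise.
    """
    vals = np.asarray(series, dtype=float)
    if vals.size < 3:
        raise InsufficientDataError(
            f"leak check needs >= 3 cycles, got {vals.size}")
    retained = vals[1:]
    vmax, vmin = retained.max(), retained.min()
    if vmax <= 0:
        raise InsufficientDataError("non-positive discharge values: no signal to judge")
    drift = (vmax - vmin) / vmax * 100.0
    steps = np.diff(retained)
    frac_neg = float(np.mean(steps < 0)) if steps.size else 0.0
    decreasing = frac_neg >= decreasing_step_fraction
    if drift > leak_drift_pct and decreasing:
        status = "leaking"
    elif drift <= tight_drift_pct:
        status = "tight"
    else:
        status = "suspicious"
    return LeakVerdict(status=status, max_drift_pct=float(drift),
                       monotone_decreasing=decreasing, n_cycles=int(vals.size))
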