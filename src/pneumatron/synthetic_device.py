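"""Simulator of the automated pneumatic measurement cycle.

The instrument repeatedly evacuates a fixed discharge tube to a partial
vacuum (default 40 kPa absolute), logs the pressure while gas diffuses
in from the connected, dehydrating plant sample, vents, and waits for
the next cycle (default every 15 min).  If the pressure climbs back to
the restart threshold (default 90 kPa) mid-measurement the pump pulls a
new vacuum, which invalidates that interval.

The sample is modelled as a gas reservoir at atmospheric pressure whose
size tracks drought-induced embolism: cut-open conduits and permanently
gas-filled spaces contribute a constant "dead" volume (so the minimum
discharge is non-zero), while embolisable conduits contribute in
proportion to the embolised fraction

    f(psi) = 1 / (1 + exp(a * (psi - psi50)))

with ``psi`` the xylem water potential (MPa, negative), ``psi50`` the
potential at 50% embolism, and ``a`` the sigmoid steepness.  Within a
cycle the tube pressure relaxes first-order toward the two-reservoir
mass-balance equilibrium

    p_eq = (p_i * V_t + P_atm * V_s) / (V_t + V_s)

at rate ``k`` (dp/dt = k (p_eq - p) + leak).  This kinetics is a
simulator convention — the simplest model consistent with gas extraction
from embolised conduits being fast — not a measured instrument law.
Between cycles the sample's gas fully re-equilibrates with the
atmosphere, which is what the 15-min minimum interval is for.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .records import PressureTrace

__all__ = [
    "DeviceConfig",
    "SampleModel",
    "SimTruth",
    "embolised_fraction",
    "simulate_cycle",
    "simulate_dehydration_experiment",
    "simulate_leak_test",
]

#: default wall-clock start of simulated experiments
DEFAULT_START = datetime(2024, 1, 1, 8, 0, 0)


@dataclass(frozen=True)
class DeviceConfig:
    """Instrument settings for the automated mode.

    Parameters
    ----------
    tube_volume : float
        Discharge-tube (reservoir) volume in mL.  Required; it is the
        one hardware dimension the user must adapt to the sample.
    vacuum_target_abs : float
        Absolute pressure (kPa) the pump pulls at cycle start.
    restart_threshold_abs : float
        Absolute pressure (kPa) at which the pump re-evacuates
        mid-measurement.
    extraction_duration : float
        Seconds of logged extraction per cycle (the recommended
        analysis endpoint is 15 s even when 60 s are logged).
    vent_duration : float
        Seconds the solenoid vents to atmosphere after extraction
        (not logged).
    cycle_interval : float
        Minutes between cycle starts.
    sampling_rate : float
        Samples per second (the firmware blinks every 0.5 s -> 2 Hz).
    atm_pressure : float
        Ambient absolute pressure, kPa.
    temperature : float
        Gas temperature, K (a per-experiment constant).
    sensor_noise_sd : float
        Additive Gaussian sensor noise, kPa (1 sd per sample).
    gas_constant : float
        Molar gas constant, J mol^-1 K^-1.
    """

    tube_volume: float
    vacuum_target_abs: float = 40.0
    restart_threshold_abs: float = 90.0
    extraction_duration: float = 60.0
    vent_duration: float = 5.0
    cycle_interval: float = 15.0
    sampling_rate: float = 2.0
    atm_pressure: float = 101.3
    temperature: float = 293.15
    sensor_noise_sd: float = 0.05
    gas_constant: float = 8.3145

    def __post_init__(self) -> None:
        if not (self.vacuum_target_abs < self.restart_threshold_abs < self.atm_pressure):
            raise ConfigError(
                "require vacuum_target_abs < restart_threshold_abs < atm_pressure, "
                f"got {self.vacuum_target_abs} / {self.restart_threshold_abs} / "
                f"{self.atm_pressure} kPa"
            )
        if self.tube_volume <= 0:
            raise ConfigError("tube_volume must be positive (mL)")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive (Hz)")
        if self.extraction_duration <= 0 or self.cycle_interval <= 0:
            raise ConfigError("durations must be positive")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive (K)")
        if self.sensor_noise_sd < 0:
            raise ConfigError("sensor_noise_sd must be non-negative")


@dataclass(frozen=True)
class SampleModel:
    """Generative model of a dehydrating sample.

    ``psi_schedule`` is a piecewise-linear water-potential trajectory as
    (time_s, psi_MPa) breakpoints, non-increasing in psi.  ``v_emb_max``
    is the gas space of all embolisable conduits at atmospheric pressure
    (µL) and ``v_dead`` the always-gas-filled space (cut-open conduits
    plus permanently connected volumes), which sets a non-zero minimum
    discharge.  ``equilibration_rate_k`` is the first-order rate (s^-1)
    at which tube pressure approaches the mass-balance equilibrium, and
    ``leak_rate`` (kPa/s) models a leaky connection (0 = tight).
    """

    psi50_true: float = -3.0
    slope_a_true: float = 2.0
    v_emb_max: float = 400.0
    v_dead: float = 40.0
    equilibration_rate_k: float = 0.1
    leak_rate: float = 0.0
    psi_schedule: tuple = ((0.0, -0.5), (36000.0, -6.5))

    def __post_init__(self) -> None:
        if self.psi50_true >= 0:
            raise ConfigError("psi50_true must be negative (MPa)")
        if self.slope_a_true <= 0:
            raise ConfigError("slope_a_true must be positive (MPa^-1)")
        if self.v_emb_max < 0 or self.v_dead < 0:
            raise ConfigError("gas volumes must be non-negative (uL)")
        if self.equilibration_rate_k <= 0:
            raise ConfigError("equilibration_rate_k must be positive (s^-1)")
        sched = tuple((float(t), float(p)) for t, p in self.psi_schedule)
        object.__setattr__(self, "psi_schedule", sched)
        times = [t for t, _ in sched]
        psis = [p for _, p in sched]
        if len(sched) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigError("psi_schedule needs >= 2 strictly increasing times")
        if any(b > a for a, b in zip(psis, psis[1:])):
            raise ConfigError("psi_schedule must be non-increasing in psi")
        if any(p > 0 for p in psis):
            raise ConfigError("psi_schedule values must be <= 0 MPa")

    @property
    def schedule_end(self) -> float:
        return self.psi_schedule[-1][0]

    def psi_at(self, t: float) -> float:
        """Water potential (MPa) at time ``t`` seconds, linear between breakpoints."""
        times = np.array([p[0] for p in self.psi_schedule])
        psis = np.array([p[1] for p in self.psi_schedule])
        if t < times[0] or t > times[-1]:
            raise ValueError(f"t={t} s outside psi_schedule [{times[0]}, {times[-1]}]")
        return float(np.interp(t, times, psis))


@dataclass
class SimTruth:
    """Ground-truth sidecar written next to a simulated log.

    Per-cycle water potential and embolised fraction at cycle start,
    plus the generating sigmoid parameters and the full-equilibration
    discharge volumes GDmin/GDmax (for V_s = v_dead and
    v_dead + v_emb_max) that anchor parameter-recovery tests.
    """

    psi50_true: float
    slope_a_true: float
    gd_min_true: float
    gd_max_true: float
    cycle_times_s: list = field(default_factory=list)
    cycle_psi: list = field(default_factory=list)
    cycle_fraction: list = field(default_factory=list)

    def __post_init__(self) -> None:
        frac = np.asarray(self.cycle_fraction, dtype=float)
        if frac.size:
            if np.any(frac < 0) or np.any(frac > 1):
                raise ValueError("embolised fractions must lie in [0, 1]")
            if np.any(np.diff(frac) < -1e-12):
                raise ValueError("embolised fraction must be non-decreasing over cycles")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def embolised_fraction(psi: float, sample: SampleModel):
    """Fraction of embolisable conduits that are gas-filled at ``psi``.

    The generative sigmoid ``1 / (1 + exp(a (psi - psi50)))``: 0.5 at
    psi50, -> 1 as psi -> -inf.  Monotonically non-increasing in psi.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > 0):
        raise ValueError("water potential must be <= 0 MPa")
    out = 1.0 / (1.0 + np.exp(sample.slope_a_true * (psi - sample.psi50_true)))
    return float(out) if out.ndim == 0 else out


def _equilibrium_pressure(p_i: float, v_t_ul: float, v_s_ul: float, p_atm: float) -> float:
    # isothermal mixing of tube gas at p_i with sample gas at p_atm
    if v_s_ul == 0:
        return p_i
    return (p_i * v_t_ul + p_atm * v_s_ul) / (v_t_ul + v_s_ul)


def simulate_cycle(
    config: DeviceConfig,
    available_gas_volume: float,
    leak_rate: float = 0.0,
    rng_seed: int | np.random.Generator | None = None,
    equilibration_rate: float = 0.1,
    measurement_id: int = 1,
    start_datetime: datetime = DEFAULT_START,
) -> PressureTrace:
    """Simulate one extraction phase and return its pressure trace.

    ``available_gas_volume`` is the sample-side gas space V_s in µL at
    atmospheric pressure.  Pressure relaxes from the vacuum target
    toward ``p_eq = (p_i V_t + P_atm V_s)/(V_t + V_s)`` with first-order
    rate ``equilibration_rate`` plus a constant ``leak_rate`` drift
    (kPa/s).  If a sample would exceed the restart threshold it is
    recorded clipped at the threshold with a pump event, and relaxation
    restarts from the vacuum target.  The trace has exactly
    ``extraction_duration * sampling_rate`` samples and is deterministic
    given ``rng_seed``.
    """
    for name, val in (("available_gas_volume", available_gas_volume),
                      ("leak_rate", leak_rate),
                      ("equilibration_rate", equilibration_rate)):
        if not math.isfinite(val):
            raise ValueError(f"{name} must be finite")
    if available_gas_volume < 0:
        raise ValueError("available_gas_volume must be >= 0")
    if equilibration_rate <= 0:
        raise ValueError("equilibration_rate must be positive")

    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed

    n = int(round(config.extraction_duration * config.sampling_rate))
    times = np.arange(n) / config.sampling_rate
    v_t_ul = config.tube_volume * 1000.0
    p_eq = _equilibrium_pressure(
        config.vacuum_target_abs, v_t_ul, available_gas_volume, config.atm_pressure
    )
    k = equilibration_rate
    # closed form of dp/dt = k (p_eq - p) + leak: shifted exponential
    p_inf = p_eq + leak_rate / k

    pressures = np.empty(n)
    events: list[int] = []
    p_start = config.vacuum_target_abs
    t_start = 0.0
    for j, t in enumerate(times):
        p = p_inf - (p_inf - p_start) * math.exp(-k * (t - t_start))
        if p >= config.restart_threshold_abs:
            pressures[j] = config.restart_threshold_abs
            events.append(j)
            p_start = config.vacuum_target_abs
            t_start = t
        else:
            pressures[j] = p
    if config.sensor_noise_sd > 0:
        pressures = pressures + rng.normal(0.0, config.sensor_noise_sd, size=n)
    np.clip(pressures, 1e-6, 120.0, out=pressures)

    return PressureTrace(
        measurement_id=measurement_id,
        start_datetime=start_datetime,
        times=times,
        pressures=pressures,
        pump_events=np.array(events, dtype=int),
    )


def _full_equilibration_gd_ul(config: DeviceConfig, v_s_ul: float) -> float:
    # discharge volume (uL at atmospheric) once the tube fully equilibrates
    v_t_ul = config.tube_volume * 1000.0
    p_eq = _equilibrium_pressure(config.vacuum_target_abs, v_t_ul, v_s_ul,
                                 config.atm_pressure)
    return (p_eq - config.vacuum_target_abs) * v_t_ul / config.atm_pressure


def simulate_dehydration_experiment(
    config: DeviceConfig,
    sample: SampleModel,
    duration_hours: float,
    rng_seed: int | None = 0,
    start_datetime: datetime = DEFAULT_START,
) -> tuple[list[PressureTrace], SimTruth]:
    """Run the automated mode on a dehydrating sample.

    One cycle starts every ``cycle_interval`` minutes from t=0 until
    ``duration_hours``; at each start the sample's available gas is
    ``v_dead + f(psi(t)) * v_emb_max`` (the gas space re-equilibrates
    with the atmosphere between cycles).  Returns the pressure traces
    and a matching :class:`SimTruth`; byte-identical outputs for the
    same seed.
    """
    duration_s = duration_hours * 3600.0
    if sample.schedule_end < duration_s - 1e-9:
        raise ConfigError(
            f"psi_schedule ends at {sample.schedule_end} s but the experiment "
            f"lasts {duration_s} s; extend the schedule"
        )
    rng = np.random.default_rng(rng_seed)
    interval_s = config.cycle_interval * 60.0
    n_cycles = int(duration_s / interval_s)

    traces: list[PressureTrace] = []
    truth = SimTruth(
        psi50_true=sample.psi50_true,
        slope_a_true=sample.slope_a_true,
        gd_min_true=_full_equilibration_gd_ul(config, sample.v_dead),
        gd_max_true=_full_equilibration_gd_ul(
            config, sample.v_dead + sample.v_emb_max),
    )
    for c in range(n_cycles):
        t_c = c * interval_s
        psi = sample.psi_at(t_c)
        f = embolised_fraction(psi, sample)
        v_s = sample.v_dead + f * sample.v_emb_max
        trace = simulate_cycle(
            config,
            available_gas_volume=v_s,
            leak_rate=sample.leak_rate,
            rng_seed=rng,
            equilibration_rate=sample.equilibration_rate_k,
            measurement_id=c + 1,
            start_datetime=start_datetime + timedelta(seconds=t_c),
        )
        traces.append(trace)
        truth.cycle_times_s.append(t_c)
        truth.cycle_psi.append(psi)
        truth.cycle_fraction.append(f)
    return traces, truth


def simulate_leak_test(
    config: DeviceConfig,
    n_cycles: int = 10,
    v_blocked_ul: float = 1000.0,
    per_cycle_decline: float = 0.0,
    leak_rate: float = 0.0,
    rng_seed: int | None = 0,
    start_datetime: datetime = DEFAULT_START,
) -> list[PressureTrace]:
    """Simulate a blocked-tube leak test run.

    The connection tubing is blocked off, leaving a fixed trapped gas
    space ``v_blocked_ul`` (µL).  A tight system then returns a
    near-constant discharge every cycle, apart from the first cycle,
    which is close to zero (the trapped space is still equilibrating
    when the run starts).

    ``per_cycle_decline`` is the fractional cycle-on-cycle decay of the
    apparent discharge that leaking systems show in blocked tests
    (readings drifting down regularly).  It is a phenomenological
    emulation of that documented failure signature, not a consequence
    of the two-reservoir kinetics — which is stationary across cycles
    and cannot reproduce it.  ``leak_rate`` (kPa/s) is the within-cycle
    pressure drift passed through to each cycle.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if not 0.0 <= per_cycle_decline < 1.0:
        raise ValueError("per_cycle_decline must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    interval_s = config.cycle_interval * 60.0
    traces = []
    for c in range(n_cycles):
        v_s = 0.0 if c == 0 else v_blocked_ul * (1.0 - per_cycle_decline) ** (c - 1)
        traces.append(simulate_cycle(
            config,
            available_gas_volume=v_s,
            leak_rate=leak_rate,
            rng_seed=rng,
            measurement_id=c + 1,
            start_datetime=start_datetime + timedelta(seconds=c * interval_s),
        ))
    return traces
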