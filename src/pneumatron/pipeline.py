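"""End-to-end orchestration: raw log + water potentials -> VCResult.

This is the library equivalent of the released analysis workflow: read
the log, extract per-cycle endpoints, convert to gas discharge, put
water potential on the same 15-min temporal scale, normalise, fit and
derive traits.  The CLI's ``analyze`` command is a thin wrapper over
:func:`analyze_experiment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import log_io, pneumatics, vulnerability
from .config import AnalysisConfig
from .errors import InsufficientDataError
from .records import MeasurementCycle
from .synthetic_device import DeviceConfig

__all__ = ["AnalysisReport", "analyze_experiment", "analyze_frames"]


@dataclass
class AnalysisReport:
    """Everything one analysis run produced, for reporting and plotting."""

    result: vulnerability.VCResult
    points: pd.DataFrame          # measurement_id, datetime, psi, gd (ul), pgd
    gd_series: pd.DataFrame       # all unflagged cycles, incl. outside psi range
    psi_grid: pd.DataFrame
    psi_obs: pd.DataFrame
    n_cycles: int = 0
    n_flagged: int = 0
    n_unmatched: int = 0

    @property
    def qc(self) -> dict:
        return {
            "n_cycles": self.n_cycles,
            "n_flagged_excluded": self.n_flagged,
            "n_unmatched_dropped": self.n_unmatched,
            "n_fit_points": self.result.n_points,
            "plateau_ok": self.result.plateau_ok,
        }


def analyze_frames(
    cycles: list[MeasurementCycle],
    psi_obs: pd.DataFrame,
    device: DeviceConfig,
    analysis: AnalysisConfig,
) -> AnalysisReport:
    """Analysis chain starting from extracted cycles and psi observations."""
    gd_df, n_flagged = pneumatics.gas_discharge_series(
        cycles, tube_volume=device.tube_volume,
        temperature=device.temperature, atm_pressure=device.atm_pressure)
    if len(gd_df) < 6:
        raise InsufficientDataError(
            f"only {len(gd_df)} usable cycles after flagging; need >= 6")

    grid = vulnerability.interpolate_psi(psi_obs, grid_interval=analysis.grid_interval)
    matched, n_unmatched = vulnerability.match_psi_to_cycles(
        grid, gd_df.rename(columns={"ul_atm": "gd"}),
        tolerance=analysis.match_tolerance)
    if len(matched) < 6:
        raise InsufficientDataError(
            f"only {len(matched)} cycles overlap the water-potential record")

    plateaus = vulnerability.detect_plateaus(
        matched["gd"].to_numpy(),
        gdmin_cycles=analysis.gdmin_cycles,
        plateau_tol=analysis.plateau_tol,
        min_cycles=analysis.plateau_min_cycles)
    matched = matched.assign(pgd=vulnerability.normalize_pgd(
        matched["gd"].to_numpy(), plateaus.gd_min, plateaus.gd_max))

    fit = vulnerability.fit_sigmoid(matched["psi"].to_numpy(),
                                    matched["pgd"].to_numpy())
    p12, p88 = vulnerability.traits_from_fit(fit.a, fit.psi50)
    near = vulnerability.nearest_traits(matched)

    result = vulnerability.VCResult(
        gd_min=plateaus.gd_min, gd_max=plateaus.gd_max, a=fit.a,
        p50_pad=fit.psi50, p12_pad=p12, p88_pad=p88,
        p50_near=near["p50_near"], p12_near=near["p12_near"],
        p88_near=near["p88_near"],
        plateau_ok=plateaus.plateau_ok,
        residual_se=fit.residual_se, n_points=fit.n_points)

    return AnalysisReport(
        result=result, points=matched, gd_series=gd_df,
        psi_grid=grid, psi_obs=psi_obs,
        n_cycles=len(cycles), n_flagged=n_flagged, n_unmatched=n_unmatched)


def analyze_experiment(
    log_path,
    psi_path,
    device: DeviceConfig,
    analysis: AnalysisConfig | None = None,
    strict: bool = False,
) -> AnalysisReport:
    """Full pipeline from files on disk to a vulnerability-curve result."""
    analysis = analysis or AnalysisConfig()
    traces = log_io.read_log(log_path, strict=strict)
    if not traces:
        raise InsufficientDataError(f"no measurement cycles in {log_path}")
    cycles = [
        log_io.extract_endpoints(
            tr, t_i=analysis.t_i, t_f=analysis.t_f, window=analysis.window,
            vacuum_target=device.vacuum_target_abs,
            start_tolerance=analysis.start_tolerance)
        for tr in traces
    ]
    psi_obs = vulnerability.read_psi_csv(psi_path)
    return analyze_frames(cycles, psi_obs, device, analysis)
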