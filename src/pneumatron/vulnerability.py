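"""Vulnerability-curve construction from gas discharge and water potential.

Sparse water-potential observations (pressure chamber or psychrometer)
are linearly interpolated onto the instrument's measurement grid, each
cycle's gas discharge is normalised between the experiment's minimum
and maximum plateaus to a percentage of gas discharged,

    PGD = 100 (GD - GDmin) / (GDmax - GDmin),

and the Pammenter-type sigmoid

    PGD(psi) = 100 / (1 + exp(a (psi - psi50)))

is fitted by nonlinear least squares.  The drought-resistance traits
psi12/psi50/psi88 come either from the fitted curve ("pad" variants)
or from the measured point nearest the target PGD ("near" variants).

A reliable GDmax plateau is essential: stopping the experiment before
the discharge flattens makes psi50 come out spuriously less negative,
so plateau detection is a first-class diagnostic here, not a footnote.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DegenerateNormalizationError,
    FitError,
    FormatError,
    InsufficientDataError,
    PlateauWarning,
)

__all__ = [
    "PSI_REQUIRED_HEADERS",
    "read_psi_csv",
    "interpolate_psi",
    "match_psi_to_cycles",
    "PlateauResult",
    "detect_plateaus",
    "normalize_pgd",
    "clamp_pgd",
    "SigmoidFit",
    "logit_initial_estimates",
    "fit_sigmoid",
    "sigmoid_pgd",
    "traits_from_fit",
    "nearest_traits",
    "VCResult",
    "write_results",
    "read_results",
]

PSI_REQUIRED_HEADERS = ("date", "hour", "psy")

RESULT_COLUMNS = [
    "p50.pad", "p12.pad", "p88.pad",
    "p50_near", "p12_near", "p88_near",
    "a", "gd_min", "gd_max", "plateau_ok",
]


def read_psi_csv(path) -> pd.DataFrame:
    """Read a water-potential file with headers "date", "hour", "psy".

    Dates are dd/mm/yyyy, hours hh:mm, and psy is the xylem water
    potential in MPa (non-positive).  Returns a frame with ``datetime``
    and ``psy`` columns sorted by time.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"water-potential file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in PSI_REQUIRED_HEADERS if c not in df.columns]
    if missing:
        raise FormatError(
            f'water-potential file {path} must define headers '
            f'"date", "hour", "psy"; missing: {missing}'
        )
    try:
        dt = pd.to_datetime(df["date"].astype(str).str.strip() + " "
                            + df["hour"].astype(str).str.strip(),
                            format="%d/%m/%Y %H:%M")
    except ValueError as exc:
        raise FormatError(
            f"timestamps in {path} must be dd/mm/yyyy and hh:mm: {exc}") from exc
    psy = pd.to_numeric(df["psy"], errors="raise").astype(float)
    if (psy > 0).any():
        raise FormatError("psy values must be <= 0 MPa (water potentials)")
    out = pd.DataFrame({"datetime": dt, "psy": psy}).sort_values("datetime")
    return out.reset_index(drop=True)


def interpolate_psi(measurements: pd.DataFrame, grid_interval: float = 15.0) -> pd.DataFrame:
    """Linear water-potential interpolation on a regular grid.

    ``measurements`` needs ``datetime`` and ``psy`` columns with
    strictly increasing timestamps.  The grid starts at the first
    observation and steps every ``grid_interval`` minutes up to the
    last; no extrapolation outside the observed range (cycles out
    there are dropped later, not guessed at).
    """
    if len(measurements) < 2:
        raise InsufficientDataError("need >= 2 water-potential measurements")
    t = pd.to_datetime(measurements["datetime"])
    if t.duplicated().any():
        raise FormatError("duplicate water-potential timestamps")
    if not t.is_monotonic_increasing:
        raise FormatError("water-potential timestamps must be increasing")
    grid = pd.date_range(t.iloc[0], t.iloc[-1],
                         freq=pd.Timedelta(minutes=float(grid_interval)))
    x = t.astype("int64").to_numpy()
    y = measurements["psy"].to_numpy(dtype=float)
    psi_hat = np.interp(grid.astype("int64").to_numpy(), x, y)
    return pd.DataFrame({"datetime": grid, "psi": psi_hat})


def match_psi_to_cycles(
    grid: pd.DataFrame,
    gd: pd.DataFrame,
    tolerance: float = 7.5,
) -> tuple[pd.DataFrame, int]:
    """Pair each discharge cycle with the nearest grid water potential.

    ``tolerance`` is the maximum time mismatch in minutes (default half
    a 15-min grid step).  Cycles without a grid point inside the
    tolerance are dropped; their count is returned and warned about.
    """
    if grid.empty or gd.empty:
        warnings.warn("no overlap between discharge cycles and psi grid")
        return gd.iloc[0:0].assign(psi=[]), len(gd)
    gd = gd.sort_values("datetime").reset_index(drop=True)
    merged = pd.merge_asof(
        gd,
        grid.sort_values("datetime").rename(columns={"datetime": "psi_time"}),
        left_on="datetime",
        right_on="psi_time",
        direction="nearest",
        tolerance=pd.Timedelta(minutes=tolerance),
    )
    dropped = int(merged["psi"].isna().sum())
    if dropped:
        warnings.warn(f"{dropped} cycle(s) had no water potential within "
                      f"{tolerance} min and were dropped")
    out = merged.dropna(subset=["psi"]).drop(columns=["psi_time"])
    if out.empty:
        warnings.warn("no overlap between discharge cycles and psi grid")
    return out.reset_index(drop=True), dropped


@dataclass(frozen=True)
class PlateauResult:
    gd_min: float
    gd_max: float
    plateau_ok: bool
    gdmax_window: int  # cycles in the accepted terminal window (0 if none)
    gdmax_rel_range: float


def detect_plateaus(
    gd_values,
    gdmin_cycles: int = 3,
    plateau_tol: float = 0.05,
    min_cycles: int = 4,
) -> PlateauResult:
    """Locate the GDmin and GDmax plateaus of a time-ordered GD series.

    GDmin is the mean of the first ``gdmin_cycles`` cycles.  GDmax is
    the mean over the longest terminal window whose relative range
    (max-min)/max stays within ``plateau_tol`` and spans at least
    ``min_cycles`` cycles.  If no such window exists the series never
    flattened — the experiment stopped too early — so ``plateau_ok``
    is False and GDmax falls back to the overall maximum, flagged
    unreliable.
    """
    gd = np.asarray(gd_values, dtype=float)
    if gd.size < 6:
        raise InsufficientDataError(
            f"plateau detection needs >= 6 cycles, got {gd.size}")
    gd_min = float(gd[:gdmin_cycles].mean())

    best_m = 0
    best_rel = math.nan
    for m in range(gd.size, min_cycles - 1, -1):
        tail = gd[-m:]
        tmax = tail.max()
        if tmax <= 0:
            continue
        rel = (tmax - tail.min()) / tmax
        if rel <= plateau_tol:
            best_m, best_rel = m, float(rel)
            break
    if best_m:
        gd_max = float(gd[-best_m:].mean())
        return PlateauResult(gd_min, gd_max, True, best_m, best_rel)
    warnings.warn(
        "no terminal GDmax plateau found: the experiment appears to have "
        "stopped prematurely; GDmax falls back to the overall maximum and "
        "derived traits are unreliable",
        PlateauWarning,
    )
    tail = gd[-min_cycles:]
    rel = float((tail.max() - tail.min()) / tail.max()) if tail.max() > 0 else math.nan
    return PlateauResult(gd_min, float(gd.max()), False, 0, rel)


def normalize_pgd(gd, gd_min: float, gd_max: float):
    """Percentage of gas discharged: 100 (GD - GDmin) / (GDmax - GDmin).

    Raw values are returned (noise can push them slightly outside
    [0, 100]); use :func:`clamp_pgd` for display.
    """
    if gd_max <= gd_min:
        raise DegenerateNormalizationError(
            f"gd_max ({gd_max}) must exceed gd_min ({gd_min}); "
            "a flat series cannot be normalised"
        )
    gd = np.asarray(gd, dtype=float)
    out = 100.0 * (gd - gd_min) / (gd_max - gd_min)
    return float(out) if out.ndim == 0 else out


def clamp_pgd(pgd):
    """Clip PGD to [0, 100]; returns (clipped, was_clamped mask)."""
    pgd = np.asarray(pgd, dtype=float)
    clipped = np.clip(pgd, 0.0, 100.0)
    return clipped, pgd != clipped


def sigmoid_pgd(psi, a: float, psi50: float):
    """Model curve PGD(psi) = 100 / (1 + exp(a (psi - psi50)))."""
    return 100.0 / (1.0 + np.exp(a * (np.asarray(psi, dtype=float) - psi50)))


@dataclass(frozen=True)
class SigmoidFit:
    a: float
    psi50: float
    residual_se: float
    n_points: int
    init_a: float
    init_psi50: float
    converged: bool = True


def logit_initial_estimates(psi, pgd) -> tuple[float, float]:
    """Closed-form starting values from the logit linearisation.

    For points strictly inside (0, 100),
    ``ln((100 - PGD)/PGD) = a psi - a psi50`` is a straight line in
    psi; its OLS slope and intercept give (a, psi50) directly.
    """
    psi = np.asarray(psi, dtype=float)
    pgd = np.asarray(pgd, dtype=float)
    inside = (pgd > 0.0) & (pgd < 100.0)
    if inside.sum() < 2 or np.unique(psi[inside]).size < 2:
        return 1.0, float(np.median(psi))
    y = np.log((100.0 - pgd[inside]) / pgd[inside])
    res = stats.linregress(psi[inside], y)
    if res.slope <= 0:
        return 1.0, float(np.median(psi))
    return float(res.slope), float(-res.intercept / res.slope)


def fit_sigmoid(psi, pgd) -> SigmoidFit:
    """Nonlinear least-squares fit of the PGD sigmoid.

    Initialised from the logit linearisation; unweighted; fitted on
    raw (unclamped) PGD.  Warns when the points do not span both
    tails (< 20% and > 80% PGD) — trait extrapolation is then shaky.
    Raises :class:`FitError` (carrying the initial estimates) on
    non-convergence or if the fitted slope violates the a > 0 sign
    convention (PGD must rise toward more negative psi).
    """
    psi = np.asarray(psi, dtype=float)
    pgd = np.asarray(pgd, dtype=float)
    if psi.size != pgd.size:
        raise ValueError("psi and pgd must have equal length")
    if psi.size < 5:
        raise InsufficientDataError(f"sigmoid fit needs >= 5 points, got {psi.size}")
    if not (np.any(pgd < 20.0) and np.any(pgd > 80.0)):
        warnings.warn(
            "PGD points do not span both tails (< 20% and > 80%): "
            "fitted traits may be poorly constrained"
        )
    a0, p0 = logit_initial_estimates(psi, pgd)
    try:
        popt, _ = optimize.curve_fit(
            sigmoid_pgd, psi, pgd, p0=[a0, p0], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"sigmoid fit did not converge: {exc}",
                       initial_estimates=(a0, p0)) from exc
    a, psi50 = float(popt[0]), float(popt[1])
    if a <= 0:
        raise FitError(
            f"fitted slope a={a:.3g} violates the sign convention (a > 0 with "
            "psi in negative MPa so PGD -> 100 as psi -> -inf)",
            initial_estimates=(a0, p0),
        )
    resid = pgd - sigmoid_pgd(psi, a, psi50)
    dof = max(psi.size - 2, 1)
    return SigmoidFit(a=a, psi50=psi50,
                      residual_se=float(np.sqrt(np.sum(resid**2) / dof)),
                      n_points=int(psi.size), init_a=a0, init_psi50=p0)


def traits_from_fit(a: float, psi50: float) -> tuple[float, float]:
    """(psi12, psi88) from the fitted sigmoid.

    Inverting the model, PGD = x at
    ``psi_x = psi50 + ln((100 - x)/x) / a``; psi12 and psi88 sit
    symmetrically (+/- ln(88/12)/a) around psi50.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    offset = math.log(88.0 / 12.0) / a
    return psi50 + offset, psi50 - offset


def nearest_traits(points: pd.DataFrame) -> dict:
    """Trait estimates from measured points nearest 12/50/88% PGD.

    Distance is in PGD; ties break toward the less negative
    (earlier-dehydration) water potential.  ``points`` needs ``psi``
    and ``pgd`` columns.
    """
    if points.empty:
        raise InsufficientDataError("no points for nearest-trait extraction")
    psi = points["psi"].to_numpy(dtype=float)
    pgd = points["pgd"].to_numpy(dtype=float)
    out = {}
    for x in (12, 50, 88):
        d = np.abs(pgd - x)
        ties = np.flatnonzero(d <= d.min() + 1e-12)
        out[f"p{x}_near"] = float(psi[ties].max())
    return out


@dataclass(frozen=True)
class VCResult:
    """Summary of one vulnerability-curve analysis."""

    gd_min: float
    gd_max: float
    a: float
    p50_pad: float
    p12_pad: float
    p88_pad: float
    p50_near: float
    p12_near: float
    p88_near: float
    plateau_ok: bool
    residual_se: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.p12_pad >= self.p50_pad >= self.p88_pad):
            raise ValueError("trait ordering violated: require p12 >= p50 >= p88")
        if self.gd_max <= self.gd_min:
            raise ValueError("gd_max must exceed gd_min")


def write_results(result: VCResult, path, provenance: dict | None = None) -> None:
    """Write the summary results.csv (field-standard column names).

    Optional provenance (config hash, version, ...) is written as
    leading ``#`` comment lines so the CSV body stays standard.
    """
    row = {
        "p50.pad": result.p50_pad, "p12.pad": result.p12_pad,
        "p88.pad": result.p88_pad, "p50_near": result.p50_near,
        "p12_near": result.p12_near, "p88_near": result.p88_near,
        "a": result.a, "gd_min": result.gd_min, "gd_max": result.gd_max,
        "plateau_ok": result.plateau_ok,
    }
    lines = [f"# {k}: {v}" for k, v in (provenance or {}).items()]
    lines.append(",".join(RESULT_COLUMNS))
    lines.append(",".join(repr(row[c]) if isinstance(row[c], float) else str(row[c])
                          for c in RESULT_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path) -> pd.DataFrame:
    """Read back a results.csv written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")
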