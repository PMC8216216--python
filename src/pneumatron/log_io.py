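"""Reading and writing instrument logs, and cycle endpoint extraction.

The log dialect is one CSV row per pressure sample:

    measurement_id,datetime,elapsed_s,pressure_kPa,pump_event

``measurement_id`` increments once per cycle, ``datetime`` is ISO 8601
at seconds precision, ``elapsed_s`` is the within-cycle time, pressures
are absolute kPa and ``pump_event`` is 1 on samples where the vacuum
pump restarted.  The on-card firmware file ("log.txt") does not fix a
column layout; this dialect is the repository standard and both the
simulator and this parser use it.

Field logs are messy: malformed rows are skipped with a warning by
default (``strict=True`` aborts instead).
"""

from __future__ import annotations

import warnings
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .records import MeasurementCycle, PressureTrace

__all__ = ["read_log", "write_log", "extract_endpoints", "cycles_to_frame"]

LOG_COLUMNS = ["measurement_id", "datetime", "elapsed_s", "pressure_kPa", "pump_event"]


def write_log(traces: Iterable[PressureTrace], path) -> None:
    """Write pressure traces in the repository log dialect."""
    lines = [",".join(LOG_COLUMNS)]
    for tr in traces:
        events = set(int(i) for i in tr.pump_events)
        for j, (t, p) in enumerate(zip(tr.times, tr.pressures)):
            stamp = (tr.start_datetime + pd.Timedelta(seconds=float(t))).replace(
                microsecond=0)
            lines.append(
                f"{tr.measurement_id},{stamp.isoformat()},{t:.3f},{p:.5f},"
                f"{1 if j in events else 0}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_log(path, strict: bool = False) -> list[PressureTrace]:
    """Parse a log file into per-cycle pressure traces.

    Traces are grouped by ``measurement_id`` and ordered by start time.
    Rows with unparseable numeric fields are skipped with a warning
    naming their line numbers (or raise :class:`FormatError` when
    ``strict``).  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"log file not found: {path}")
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"log file {path} is empty")
        return []
    missing = [c for c in LOG_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(
            f"log file {path} is missing required columns: {missing}; "
            f"expected {LOG_COLUMNS}"
        )
    if raw.empty:
        warnings.warn(f"log file {path} contains a header but no rows")
        return []

    num = pd.DataFrame({
        "measurement_id": pd.to_numeric(raw["measurement_id"], errors="coerce"),
        "elapsed_s": pd.to_numeric(raw["elapsed_s"], errors="coerce"),
        "pressure_kPa": pd.to_numeric(raw["pressure_kPa"], errors="coerce"),
        "pump_event": pd.to_numeric(raw["pump_event"], errors="coerce"),
    })
    num["datetime"] = pd.to_datetime(raw["datetime"], format="ISO8601", errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in num.index[bad]]  # +2: header + 1-based
        msg = f"{len(lines)} malformed row(s) in {path} at line(s) {lines[:20]}"
        if strict:
            raise FormatError(msg)
        warnings.warn(msg + "; skipped")
        num = num[~bad]

    traces: list[PressureTrace] = []
    for mid, grp in num.groupby("measurement_id", sort=False):
        grp = grp.sort_values("elapsed_s")
        traces.append(PressureTrace(
            measurement_id=int(mid),
            start_datetime=grp["datetime"].iloc[0].to_pydatetime(),
            times=grp["elapsed_s"].to_numpy(),
            pressures=grp["pressure_kPa"].to_numpy(),
            pump_events=np.flatnonzero(grp["pump_event"].to_numpy() > 0),
        ))
    traces.sort(key=lambda tr: tr.start_datetime)
    return traces


def extract_endpoints(
    trace: PressureTrace,
    t_i: float = 2.0,
    t_f: float = 15.0,
    window: float = 0.5,
    vacuum_target: float = 40.0,
    start_tolerance: float = 5.0,
) -> MeasurementCycle:
    """Reduce a trace to its initial/final endpoint pressures.

    ``p_i`` and ``p_f`` are means over ``[t - window, t + window]``
    around the endpoint times (window averaging beats a single sample
    against sensor noise).  The defaults skip the pump transient
    (t_i = 2 s; pull-down takes under a second) and use the recommended
    15 s extraction endpoint.  Flags: ``pump_restart`` when a pump
    event falls in (t_i, t_f], ``truncated`` when the trace ends before
    t_f (p_f then comes from the last available window), and
    ``endpoint_out_of_range`` when p_i strays more than
    ``start_tolerance`` kPa from the vacuum target.
    """
    if not (0.0 <= t_i < t_f):
        raise ValueError("require 0 <= t_i < t_f")
    if window < 0:
        raise ValueError("window must be >= 0")
    if t_i + window >= t_f - window:
        raise ValueError("endpoint windows overlap: require t_i + w < t_f - w")

    t = trace.times
    p = trace.pressures
    eps = 1e-9

    def window_mean(center: float) -> float:
        mask = (t >= center - window - eps) & (t <= center + window + eps)
        if not mask.any():
            # zero-width window between samples: nearest sample
            return float(p[np.argmin(np.abs(t - center))])
        return float(p[mask].mean())

    truncated = trace.duration < t_f - eps
    p_i = window_mean(t_i)
    if truncated:
        warnings.warn(
            f"cycle {trace.measurement_id}: trace ends at {trace.duration:.1f} s "
            f"before t_f={t_f} s; p_f taken from the last window"
        )
        p_f = window_mean(trace.duration - window)
        t_end = trace.duration
    else:
        p_f = window_mean(t_f)
        t_end = t_f

    event_times = t[trace.pump_events] if trace.pump_events.size else np.empty(0)
    pump_restart = bool(np.any((event_times > t_i) & (event_times <= t_end + eps)))
    out_of_range = abs(p_i - vacuum_target) > start_tolerance

    return MeasurementCycle(
        measurement_id=trace.measurement_id,
        start_datetime=trace.start_datetime,
        p_i=p_i,
        p_f=p_f,
        pump_restart=pump_restart,
        truncated=truncated,
        endpoint_out_of_range=out_of_range,
    )


def cycles_to_frame(cycles: Sequence[MeasurementCycle]) -> pd.DataFrame:
    """Per-cycle endpoint table (the module's CSV-ready output)."""
    return pd.DataFrame({
        "measurement_id": [c.measurement_id for c in cycles],
        "datetime": [c.start_datetime for c in cycles],
        "p_i_kPa": [c.p_i for c in cycles],
        "p_f_kPa": [c.p_f for c in cycles],
        "delta_p_kPa": [c.delta_p for c in cycles],
        "pump_restart": [c.pump_restart for c in cycles],
        "truncated": [c.truncated for c in cycles],
        "endpoint_out_of_range": [c.endpoint_out_of_range for c in cycles],
    })
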