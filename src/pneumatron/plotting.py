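"""Static output figures for an analysis run.

Four panels, written as separate files: the fitted vulnerability curve
with trait markers, raw gas discharge against water potential, gas
discharge against time, and the interpolated water-potential record.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # file output only; never a display

import matplotlib.pyplot as plt
import numpy as np

from .pipeline import AnalysisReport
from .vulnerability import sigmoid_pgd

__all__ = ["save_figures"]

FIGURE_NAMES = ("vc_curve.png", "gd_vs_psi.png", "gd_vs_time.png", "psi_vs_time.png")


def _vc_curve(report: AnalysisReport, ax) -> None:
    r = report.result
    pts = report.points
    ax.scatter(pts["psi"], pts["pgd"], s=18, color="0.3", label="measured PGD")
    psi_line = np.linspace(pts["psi"].min(), pts["psi"].max(), 300)
    ax.plot(psi_line, sigmoid_pgd(psi_line, r.a, r.p50_pad), color="tab:blue",
            label=f"fit: a={r.a:.2f}, $\\Psi_{{50}}$={r.p50_pad:.2f} MPa")
    for x, psi_x in ((12, r.p12_pad), (50, r.p50_pad), (88, r.p88_pad)):
        ax.axvline(psi_x, ls=":", color="tab:red", lw=0.8)
        ax.annotate(f"$\\Psi_{{{x}}}$", (psi_x, 5 + x * 0.6), fontsize=8)
    if not r.plateau_ok:
        ax.set_title("WARNING: no GDmax plateau — curve unreliable", color="red")
    ax.set_xlabel("water potential (MPa)")
    ax.set_ylabel("gas discharged (%)")
    ax.legend(fontsize=8)


def save_figures(report: AnalysisReport, out_dir) -> list[Path]:
    """Write the four standard figures into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    _vc_curve(report, ax)
    paths.append(out_dir / FIGURE_NAMES[0])
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report.points["psi"], report.points["gd"], s=18, color="0.3")
    ax.set_xlabel("water potential (MPa)")
    ax.set_ylabel("gas discharged (µL)")
    paths.append(out_dir / FIGURE_NAMES[1])
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(report.gd_series["datetime"], report.gd_series["ul_atm"],
            marker="o", ms=3, lw=0.8, color="0.3")
    ax.set_xlabel("time")
    ax.set_ylabel("gas discharged (µL)")
    fig.autofmt_xdate()
    paths.append(out_dir / FIGURE_NAMES[2])
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(report.psi_grid["datetime"], report.psi_grid["psi"], lw=1,
            color="tab:blue", label="15-min interpolation")
    ax.scatter(report.psi_obs["datetime"], report.psi_obs["psy"], s=25,
               color="tab:red", zorder=3, label="observations")
    ax.set_xlabel("time")
    ax.set_ylabel("water potential (MPa)")
    ax.legend(fontsize=8)
    fig.autofmt_xdate()
    paths.append(out_dir / FIGURE_NAMES[3])
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    return paths
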