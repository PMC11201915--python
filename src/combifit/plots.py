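"""Optional matplotlib figures for each analysis stage (PNG output)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def dose_response_plot(single: pd.DataFrame, path: str | Path) -> None:
    """Mean +/- SD viability vs concentration per agent and cell line."""
    plt = _pyplot()
    agents = sorted(single["agent"].unique())
    fig, axes = plt.subplots(1, len(agents), figsize=(5 * len(agents), 4), squeeze=False)
    for ax, agent in zip(axes[0], agents):
        sub = single[single["agent"] == agent]
        for line, grp in sub.groupby("cell_line"):
            stats = grp.groupby("concentration_ug_ml")["viability_pct"].agg(["mean", "std"])
            ax.errorbar(stats.index, stats["mean"], yerr=stats["std"], marker="o",
                        capsize=3, label=line)
        ax.set_xscale("log")
        ax.set_xlabel("concentration (ug/mL)")
        ax.set_ylabel("viability (%)")
        ax.set_title(agent)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def surface_plot(fits, path: str | Path, n_grid: int = 60) -> None:
    """3-D predicted-viability surfaces over the design region."""
    plt = _pyplot()
    fig = plt.figure(figsize=(6 * len(fits), 5))
    for i, fit in enumerate(fits, start=1):
        (tlo, thi), (blo, bhi) = fit.region
        tm, bp = np.meshgrid(np.linspace(tlo, thi, n_grid), np.linspace(blo, bhi, n_grid))
        y = fit.predict(tm, bp, check_region=False)
        ax = fig.add_subplot(1, len(fits), i, projection="3d")
        ax.plot_surface(tm, bp, y, cmap="viridis")
        ax.set_xlabel("TM (ug/mL)")
        ax.set_ylabel("BP (ug/mL)")
        ax.set_zlabel("viability (%)")
        ax.set_title(fit.response_name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ci_fa_plot(results, path: str | Path) -> None:
    """Combination index vs fraction affected, with the CI = 1 reference."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    fa = [r.fa for r in results]
    ci = [r.ci for r in results]
    ax.plot(fa, ci, "o")
    ax.axhline(1.0, color="k", linestyle="--", label="additivity (CI = 1)")
    ax.set_xlabel("fraction affected (fa)")
    ax.set_ylabel("combination index (CI)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def time_course_plot(timecourse: pd.DataFrame, path: str | Path) -> None:
    """Decay time courses with fitted lines per condition."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, grp in timecourse.groupby("condition"):
        stats = grp.groupby("time_h")["concentration_nmol_ml"].agg(["mean", "std"])
        ax.errorbar(stats.index, stats["mean"], yerr=stats["std"], marker="o",
                    capsize=3, label=cond)
        coef = np.polyfit(grp["time_h"], grp["concentration_nmol_ml"], 1)
        tt = np.linspace(grp["time_h"].min(), grp["time_h"].max(), 50)
        ax.plot(tt, np.polyval(coef, tt), "--", alpha=0.6)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("curcumin signal (nmol/mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
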