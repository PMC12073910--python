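"""Cosmetic age-trajectory plots (scatter + fit line + 95 % bands)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .trajectories import LinearTrajectory

__all__ = ["plot_trajectory"]


def plot_trajectory(values, ages, lin: LinearTrajectory, title: str,
                    path) -> None:
    """Scatter of estimates vs age with the OLS line and both 95 % bands."""
    fig, ax = plt.subplots(figsize=(4.5, 3.4))
    ax.scatter(ages, values, s=18, color="tab:blue", zorder=3)
    grid = lin.age_grid
    ax.plot(grid, lin.intercept + lin.slope * grid, color="k", lw=1.2)
    ax.fill_between(grid, lin.conf_low, lin.conf_high, alpha=0.3,
                    color="tab:blue", label="95% CI")
    ax.plot(grid, lin.pred_low, "k--", lw=0.8)
    ax.plot(grid, lin.pred_high, "k--", lw=0.8, label="95% prediction")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("estimate")
    ax.set_title(f"{title}  (slope p={lin.slope_p:.3f})", fontsize=9)
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
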