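"""Figures: FPT scale profile and the difference-of-smooths band."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_scale_profile", "plot_difference_smooth"]


def plot_scale_profile(profiles, selected: float | None = None,
                       path: str | Path | None = None):
    """Mean variance of log(FPT) across birds against radius."""
    fig, ax = plt.subplots(figsize=(6, 4))
    V = np.vstack([p.var_log_fpt for p in profiles])
    radii = profiles[0].radii
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(V, axis=0)
    for p in profiles:
        ax.plot(p.radii, p.var_log_fpt, color="0.8", lw=0.8)
    ax.plot(radii, mean, color="C0", lw=2, label="across-bird mean")
    if selected is not None:
        ax.axvline(selected, color="C3", ls="--", label=f"selected {selected:.0f} m")
    ax.set_xlabel("radius (m)")
    ax.set_ylabel("var log(FPT)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_difference_smooth(diff: pd.DataFrame, path: str | Path | None = None):
    """Pointwise observed-minus-simulated difference with its 95% band."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(diff["day"], diff["lo"], diff["hi"], alpha=0.3, color="C0")
    ax.plot(diff["day"], diff["D"], color="C0")
    ax.axhline(0, color="k", lw=0.8)
    sig = diff[diff["significant"]]
    if len(sig):
        ax.scatter(sig["day"], sig["D"], s=8, color="C3", zorder=3,
                   label="interval excludes 0")
        ax.legend(frameon=False)
    ax.set_xlabel("Julian day")
    ax.set_ylabel("difference in logit habitat quality\n(observed - simulated)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
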