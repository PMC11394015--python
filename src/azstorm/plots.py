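"""Figure helpers for the pipeline artifacts (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_nena_fit", "plot_sweep_contour", "plot_alpha_curve",
           "plot_mean_h", "boxplot_groups"]


def plot_nena_fit(result, ax=None):
    """Histogram of consecutive-frame NN distances with the NeNA fit."""
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(result.bin_centers, result.histogram, width=result.bin_width,
           color="0.8", label="NN distances")
    ax.plot(result.bin_centers, result.fitted, "r-",
            label=f"fit, sigma = {result.sigma:.1f} nm")
    ax.set_xlabel("nearest-neighbour distance (nm)")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_sweep_contour(sweep, ax=None):
    """Contour plot of median AZ count over the HDBSCAN parameter grid."""
    if ax is None:
        _, ax = plt.subplots()
    ms, mcs = np.meshgrid(sweep.ms_values, sweep.mcs_values)
    cs = ax.contourf(ms, mcs, sweep.median_counts, levels=12, cmap="viridis")
    plt.colorbar(cs, ax=ax, label="median AZ count")
    ax.set_xlabel("minimum samples")
    ax.set_ylabel("minimum cluster size")
    return ax


def plot_alpha_curve(curve, ax=None):
    """Median AZ area and percent step increase versus alpha."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.alphas, curve.median_area, "k.-", label="median area")
    ax.fill_between(curve.alphas, curve.q25_area, curve.q75_area,
                    color="m", alpha=0.2, label="quartiles")
    if curve.selected_alpha is not None:
        ax.axvline(curve.selected_alpha, color="b", ls="--",
                   label=f"selected alpha = {curve.selected_alpha:.0f} nm$^2$")
    ax.set_xlabel(r"alpha (nm$^2$)")
    ax.set_ylabel(r"AZ area (nm$^2$)")
    ax2 = ax.twinx()
    ax2.plot(curve.alphas, curve.pct_increase, "b.-", alpha=0.6)
    ax2.axhline(curve.threshold, color="b", ls=":")
    ax2.set_yscale("log")
    ax2.set_ylabel("area increase per step (%)")
    ax.legend(loc="lower right")
    return ax


def plot_mean_h(curve, ax=None, label=None):
    """Averaged H function with its maximum marked."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.r, curve.h, label=label)
    ax.axvline(curve.h_max_radius, ls="--", color="0.5")
    ax.axhline(0.0, ls=":", color="k")
    ax.set_xlabel("r (nm)")
    ax.set_ylabel("H(r) (nm)")
    if label:
        ax.legend()
    return ax


def boxplot_groups(groups: dict, ylabel: str = "", ax=None):
    """Boxplots with overlaid jittered points, one box per group."""
    if ax is None:
        _, ax = plt.subplots()
    names = list(groups)
    data = [np.asarray(groups[k], float) for k in names]
    ax.boxplot(data, tick_labels=names, showfliers=False)
    rng = np.random.default_rng(0)
    for i, vals in enumerate(data, start=1):
        ax.plot(i + rng.uniform(-0.15, 0.15, len(vals)), vals, ".",
                alpha=0.4, ms=3)
    ax.set_ylabel(ylabel)
    return ax
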