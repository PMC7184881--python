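"""Minimal plots: progression curves with SEM shading and binned A:P ratios."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .metrics import ProgressionProfile, RatioSeries

__all__ = ["plot_progression", "plot_ratio_series"]


def plot_progression(profile: ProgressionProfile, ax=None, title: str = ""):
    """Cohort-mean anterior/posterior/walk probabilities over time, shaded
    by standard error of the mean."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    for name, mean, sem, color in [
        ("anterior", profile.p_anterior, profile.sem_anterior, "tab:red"),
        ("posterior", profile.p_posterior, profile.sem_posterior, "tab:blue"),
        ("walk", profile.p_walk, profile.sem_walk, "black"),
    ]:
        ax.plot(profile.times, mean, color=color, label=name)
        ax.fill_between(profile.times, mean - sem, mean + sem, color=color, alpha=0.25, lw=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("behavior probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title, fontsize=9)
    return ax


def plot_ratio_series(series: RatioSeries, ax=None, title: str = ""):
    """Cohort-mean log10 A:P ratio per time bin."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.plot(series.bin_centers, series.cohort_mean(), "o-", color="tab:purple")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("log10 A:P grooming ratio")
    if title:
        ax.set_title(title, fontsize=9)
    return ax
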