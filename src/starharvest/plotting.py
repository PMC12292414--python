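"""Plots for the analysis chain (matplotlib, non-interactive friendly)."""

from __future__ import annotations

from typing import Mapping, Optional

import matplotlib

matplotlib.use("Agg")  # headless backend; figures are saved, not shown
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .clustering import ClusterResult

__all__ = ["plot_silhouette", "plot_zap_profiles", "plot_cluster_profiles"]


def plot_silhouette(curve: Mapping[int, float], k_selected: Optional[int] = None, ax=None):
    """Mean silhouette by number of clusters, with the selected k marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ks = sorted(curve)
    ax.plot(ks, [curve[k] for k in ks], "o-", color="0.3")
    if k_selected is not None:
        ax.plot([k_selected], [curve[k_selected]], "o", color="crimson", ms=9, zorder=3)
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("mean silhouette")
    ax.set_xticks(ks)
    return ax


def plot_zap_profiles(profiles: pd.DataFrame, ax=None, color="0.4"):
    """Participant zap rates by target similarity rank: individual lines plus
    the cohort mean."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    cols = [f"rate_{r}" for r in (1, 2, 3, 4)]
    x = np.arange(1, 5)
    for _, row in profiles[cols].iterrows():
        ax.plot(x, row.values, color=color, alpha=0.12, lw=0.8)
    ax.plot(x, profiles[cols].mean().values, "o-", color="black", lw=2, label="mean")
    ax.set_xlabel("target similarity rank (1 = most similar)")
    ax.set_ylabel("p(zap | opportunity)")
    ax.set_xticks(x)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    return ax


def plot_cluster_profiles(result: ClusterResult, ax=None):
    """Mean unscaled zap-rate profile of each discovered cluster."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    x = np.arange(1, 5)
    for cluster, row in result.cluster_profiles.iterrows():
        ax.plot(
            x,
            row.values,
            "o-",
            label=f"cluster {cluster} (n={result.cluster_sizes[int(cluster) - 1]})",
        )
    ax.set_xlabel("target similarity rank (1 = most similar)")
    ax.set_ylabel("p(zap | opportunity)")
    ax.set_xticks(x)
    ax.legend(frameon=False, fontsize=8)
    return ax
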