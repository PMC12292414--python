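"""Rule discovery: k-means on scaled zap profiles with silhouette selection.

Each participant is one standardized 4-vector (zap rates toward targets
ordered by similarity).  K-means is run for each candidate k with many
restarts; the mean silhouette scores each k, and the number of clusters is
the smallest k whose silhouette is within a plateau tolerance of the
maximum (with tolerance 0 this is the argmax).  Cluster behaviour is then
characterized on the *unscaled* rates, so the discovered rules are readable
in probability units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterResult",
    "silhouette_curve",
    "select_k",
    "cluster_profiles",
    "discover_rules",
]

RATE_COLS = [f"rate_{r}" for r in (1, 2, 3, 4)]


def _as_matrix(matrix) -> tuple[np.ndarray, list]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), list(matrix.index)
    X = np.asarray(matrix, dtype=float)
    return X, list(range(len(X)))


def silhouette_curve(
    matrix,
    k_max: int = 8,
    n_restarts: int = 50,
    seed: int = 0,
) -> dict[int, float]:
    """Mean silhouette of the best-of-``n_restarts`` k-means fit for each
    k in 2..k_max (capped at n-1)."""
    X, _ = _as_matrix(matrix)
    n = len(X)
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    k_max = min(k_max, n - 1)
    curve: dict[int, float] = {}
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            curve[k] = -1.0
            continue
        curve[k] = float(silhouette_score(X, labels))
    return curve


def select_k(curve: Mapping[int, float], plateau_tol: float = 0.02) -> int:
    """Smallest k whose mean silhouette is within ``plateau_tol`` of the
    curve's maximum: the peak-or-plateau rule (tolerance 0 gives the peak)."""
    if not curve:
        raise ValueError("empty silhouette curve")
    best = max(curve.values())
    return min(k for k, s in sorted(curve.items()) if s >= best - plateau_tol)


@dataclass
class ClusterResult:
    """A rule-discovery solution.

    Clusters are numbered 1..k in decreasing size (ties broken by the
    smallest participant index they contain); ``cluster_profiles`` holds
    each cluster's mean unscaled zap-rate 4-vector.
    """

    k_selected: int
    silhouette_by_k: dict[int, float]
    assignments: pd.Series  # participant -> cluster label (1..k)
    centroids: np.ndarray  # in the scaled space, row i = cluster i+1
    cluster_profiles: pd.DataFrame  # index cluster, columns rate_1..rate_4
    cluster_sizes: list[int]

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != len(self.assignments):
            raise ValueError("cluster sizes must sum to the number of participants")
        for v in self.silhouette_by_k.values():
            if not -1.0 <= v <= 1.0:
                raise ValueError("silhouette values must lie in [-1, 1]")

    def silhouette_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": list(self.silhouette_by_k), "mean_silhouette": list(self.silhouette_by_k.values())}
        )

    def write(self, stem: str | Path) -> tuple[Path, Path, Path]:
        """JSON summary, assignments CSV and silhouette-curve CSV."""
        stem = Path(stem)
        json_path = stem.with_suffix(".json")
        assign_path = stem.parent / (stem.name + "_assignments.csv")
        curve_path = stem.parent / (stem.name + "_silhouette.csv")
        json_path.write_text(
            json.dumps(
                {
                    "k_selected": self.k_selected,
                    "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
                    "cluster_sizes": self.cluster_sizes,
                    "centroids": self.centroids.tolist(),
                    "cluster_profiles": self.cluster_profiles.to_dict(orient="index"),
                },
                indent=2,
            )
        )
        self.assignments.rename("cluster").to_frame().reset_index(names="participant_id").to_csv(
            assign_path, index=False
        )
        self.silhouette_frame().to_csv(curve_path, index=False)
        return json_path, assign_path, curve_path


def cluster_profiles(
    matrix,
    k: int,
    unscaled_profiles: pd.DataFrame,
    seed: int = 0,
    n_restarts: int = 50,
    silhouette_by_k: Optional[dict[int, float]] = None,
) -> ClusterResult:
    """Final k-means fit plus characterization on unscaled zap rates.

    ``matrix`` is the scaled profile matrix (participants x 4);
    ``unscaled_profiles`` the wide rate table from
    :func:`starharvest.features.zap_profiles` (only the rows present in
    ``matrix`` are used).
    """
    X, index = _as_matrix(matrix)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw_labels = km.fit_predict(X)
    # renumber clusters 1..k by decreasing size; ties by first participant index
    order = sorted(
        range(k),
        key=lambda c: (-(raw_labels == c).sum(), int(np.argmax(raw_labels == c))),
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in raw_labels])
    assignments = pd.Series(labels, index=pd.Index(index, name="participant_id"))
    centroids = km.cluster_centers_[order]
    rates = unscaled_profiles.loc[index, RATE_COLS]
    prof = rates.groupby(labels).mean()
    prof.index.name = "cluster"
    sizes = [int((labels == c).sum()) for c in range(1, k + 1)]
    return ClusterResult(
        k_selected=k,
        silhouette_by_k=dict(silhouette_by_k or {}),
        assignments=assignments,
        centroids=centroids,
        cluster_profiles=prof,
        cluster_sizes=sizes,
    )


def discover_rules(
    matrix,
    unscaled_profiles: pd.DataFrame,
    k_max: int = 8,
    n_restarts: int = 50,
    plateau_tol: float = 0.02,
    seed: int = 0,
) -> ClusterResult:
    """Silhouette curve, peak/plateau k selection, and final clustering."""
    curve = silhouette_curve(matrix, k_max=k_max, n_restarts=n_restarts, seed=seed)
    k = select_k(curve, plateau_tol=plateau_tol)
    return cluster_profiles(
        matrix,
        k,
        unscaled_profiles,
        seed=seed,
        n_restarts=n_restarts,
        silhouette_by_k=curve,
    )
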