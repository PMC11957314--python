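"""Induction statistic, perturbation filtering, and profile clustering.

Induction is the percentage of a normalized profile's features whose
absolute value exceeds a threshold (3 robust-MAD units by default); it is a
scalar measure of how strongly a treatment perturbs morphology.  Profiles
with induction at or below 20% are conventionally dropped before clustering,
which uses agglomerative linkage on either Pearson dissimilarity (1 - r,
so anti-correlated phenotypes are maximally distant) or Euclidean distance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .profiling import ProfileMatrix

log = logging.getLogger(__name__)

LINKAGE_METHODS = ("average", "single", "complete")
METRICS = ("pearson", "euclidean")


@dataclass
class ClusterResult:
    """Agglomerative merge tree over a set of profiles."""

    linkage_matrix: np.ndarray  # scipy linkage encoding (heights + members)
    order: np.ndarray  # leaves in dendrogram order
    labels: list  # row identifiers, aligned with input rows
    method: str
    metric: str

    def flat_labels(self, k: int) -> np.ndarray:
        """Cut the tree into ``k`` flat clusters (1-based labels)."""
        return hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")


def compute_induction(z, z_thresh: float = 3.0) -> float:
    """Percentage of features with ``|z|`` strictly greater than ``z_thresh``."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("induction of an empty profile is undefined")
    if not np.isfinite(z).all():
        raise ValueError("profile contains non-finite values")
    return 100.0 * float(np.count_nonzero(np.abs(z) > z_thresh)) / z.size


def add_induction(pm: ProfileMatrix, z_thresh: float = 3.0) -> pd.Series:
    """Induction of every profile row, as a Series aligned with ``pm.data``."""
    X = pm.matrix()
    values = 100.0 * (np.abs(X) > z_thresh).sum(axis=1) / X.shape[1]
    return pd.Series(values, index=pm.data.index, name="induction_pct")


def filter_by_induction(
    pm: ProfileMatrix, min_induction: float = 20.0, z_thresh: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split profiles into (kept, excluded) by strict induction threshold.

    A profile is kept only when its induction is strictly greater than
    ``min_induction`` — boundary values are excluded.  Both frames carry an
    ``induction_pct`` column.
    """
    induction = add_induction(pm, z_thresh=z_thresh)
    data = pm.data.copy()
    data["induction_pct"] = induction
    keep = induction > min_induction
    return data.loc[keep], data.loc[~keep]


def pearson_dissimilarity(X: np.ndarray) -> np.ndarray:
    """Pairwise ``1 - Pearson r`` between rows; errors on constant rows."""
    X = np.asarray(X, dtype=float)
    if (X.std(axis=1) == 0).any():
        bad = int(np.flatnonzero(X.std(axis=1) == 0)[0])
        raise ValueError(f"row {bad} is constant; Pearson metric undefined")
    d = 1.0 - np.corrcoef(X)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def cluster_profiles(
    rows, linkage: str = "average", metric: str = "pearson", labels=None
) -> ClusterResult:
    """Hierarchically cluster profile rows.

    ``rows`` may be a :class:`ProfileMatrix`, a DataFrame slice carrying
    feature columns only, or a plain array.  Ties in the agglomeration are
    resolved deterministically by scipy's ordering of the condensed distance
    matrix (row-index order).
    """
    if isinstance(rows, ProfileMatrix):
        X = rows.matrix()
        if labels is None and "compound" in rows.data.columns:
            labels = [
                f"{c}@{g:.3g}" if not v else "VEHICLE"
                for c, g, v in zip(
                    rows.data["compound"],
                    rows.data["concentration_m"],
                    rows.data["vehicle"],
                )
            ]
    elif isinstance(rows, pd.DataFrame):
        X = rows.to_numpy(dtype=float)
        if labels is None:
            labels = list(rows.index)
    else:
        X = np.asarray(rows, dtype=float)
    if labels is None:
        labels = list(range(len(X)))
    if len(X) < 2:
        raise ValueError("clustering needs at least 2 rows")
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")

    if metric == "pearson":
        condensed = squareform(pearson_dissimilarity(X), checks=False)
    else:
        condensed = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.leaves_list(Z)
    return ClusterResult(
        linkage_matrix=Z,
        order=np.asarray(order),
        labels=list(labels),
        method=linkage,
        metric=metric,
    )


def clip_for_display(m, bound: float = 8.0) -> np.ndarray:
    """Clamp values to ``[-bound, +bound]`` for heatmap export only."""
    if bound <= 0:
        raise ValueError("clip bound must be positive")
    return np.clip(np.asarray(m, dtype=float), -bound, bound)


def export_clustergram(
    result: ClusterResult,
    pm: ProfileMatrix,
    png_path,
    csv_path,
    clip_bound: float = 8.0,
) -> pd.DataFrame:
    """Write a clustered heatmap (PNG) and its ordered, clipped matrix (CSV).

    Rows follow ``result``'s dendrogram order; columns are clustered with the
    same linkage/metric (falling back to Euclidean if a feature is constant).
    The clipping is display-only and never feeds back into analysis.
    """
    X = pm.matrix()
    if len(X) != len(result.labels):
        raise ValueError("cluster result does not match the profile matrix")
    row_order = result.order
    try:
        col_res = cluster_profiles(X.T, linkage=result.method, metric=result.metric)
        col_order = col_res.order
    except ValueError:
        col_res = cluster_profiles(X.T, linkage=result.method, metric="euclidean")
        col_order = col_res.order

    clipped = clip_for_display(X, clip_bound)[np.ix_(row_order, col_order)]
    ordered = pd.DataFrame(
        clipped,
        index=[result.labels[i] for i in row_order],
        columns=[pm.features[j] for j in col_order],
    )
    ordered.rename_axis("profile").to_csv(csv_path)

    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.03 * len(pm.features)), max(4.0, 0.18 * len(X)))
    )
    vmax = clip_bound
    mesh = ax.pcolormesh(clipped, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_yticks(np.arange(len(row_order)) + 0.5)
    ax.set_yticklabels(ordered.index, fontsize=5)
    ax.set_xticks([])
    ax.set_xlabel(f"{len(pm.features)} features ({result.metric} ordered)")
    fig.colorbar(mesh, ax=ax, label="robust Z (clipped)")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return ordered
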