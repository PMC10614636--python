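"""K-means clustering of regions by eigencentrality profile, with elbow selection.

Regions are clustered on their raw per-comparison eigencentrality vectors
(the six comparison columns only — the Average column is a summary, not a
feature, and all columns already share the eigencentrality scale, so no
standardisation is applied).  The cluster count is chosen by the elbow
method, operationalised as the k with maximum discrete curvature (second
difference) of the within-cluster sum-of-squares curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .centrality_profile import CentralityProfileMatrix
from .errors import ValidationError

__all__ = ["ClusterResult", "kmeans", "elbow_select_k", "cluster_report", "cluster"]


def kmeans(
    profiles: np.ndarray, k: int, seed: int, n_init: int = 100
) -> tuple[np.ndarray, float]:
    """Euclidean k-means, best of ``n_init`` restarts by inertia.

    Returns 1-based labels and the total within-cluster sum of squares.
    Deterministic given ``seed``.
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2:
        raise ValidationError("profiles must be a 2-D matrix")
    if not np.all(np.isfinite(x)):
        raise ValidationError("profiles contain non-finite values")
    if not 1 <= k <= x.shape[0]:
        raise ValidationError(f"k={k} outside [1, {x.shape[0]}]")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    return km.labels_ + 1, float(km.inertia_)


def elbow_select_k(
    profiles: np.ndarray,
    k_range: Sequence[int] = range(1, 11),
    seed: int = 0,
    n_init: int = 100,
) -> tuple[int, dict[int, float]]:
    """Select k at the point of maximum curvature of the inertia curve.

    ``k_range`` must be contiguous and contain at least 3 values (the second
    difference needs both neighbours); the selected k is always interior.
    Ties go to the smallest k.
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValidationError("k_range must contain at least 3 values for a curvature estimate")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValidationError("k_range must be contiguous and increasing")
    x = np.asarray(profiles, dtype=float)
    if ks[0] < 1 or ks[-1] > x.shape[0]:
        raise ValidationError(f"k_range {ks[0]}..{ks[-1]} outside [1, {x.shape[0]}]")
    curve = {k: kmeans(x, k, seed=seed, n_init=n_init)[1] for k in ks}
    w = np.array([curve[k] for k in ks])
    d2 = w[:-2] - 2 * w[1:-1] + w[2:]
    k_star = ks[1 + int(np.argmax(d2))]
    return k_star, curve


@dataclass(frozen=True)
class ClusterResult:
    """Region -> cluster assignment plus the inertia curve it was selected from."""

    k: int
    labels: np.ndarray = field(repr=False)  # 1-based, aligned to region order
    region_names: tuple[str, ...]
    inertia_curve: Mapping[int, float]
    seed: int
    n_init: int

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.region_names):
            raise ValidationError("label/region length mismatch")
        if len(np.unique(self.labels)) != self.k:
            raise ValidationError(f"labels take {len(np.unique(self.labels))} values, expected k={self.k}")


def cluster(
    profiles: CentralityProfileMatrix,
    seed: int,
    k: int | None = None,
    k_range: Sequence[int] = range(1, 11),
    n_init: int = 100,
) -> ClusterResult:
    """Cluster regions on the comparison columns; choose k by elbow unless given.

    With fewer than 3 candidate k values (a union of only 1-2 regions) the
    curvature criterion is undefined; each region then becomes its own
    cluster, which is the only informative assignment at that size.
    """
    x = profiles.values
    ks = [kk for kk in k_range if kk <= x.shape[0]]
    if k is None and len(ks) < 3:
        k = x.shape[0]
        curve = {kk: kmeans(x, kk, seed=seed, n_init=n_init)[1] for kk in ks}
    elif k is None:
        k, curve = elbow_select_k(x, ks, seed=seed, n_init=n_init)
    else:
        curve = {kk: kmeans(x, kk, seed=seed, n_init=n_init)[1] for kk in ks}
    labels, _ = kmeans(x, k, seed=seed, n_init=n_init)
    # duplicate profile rows can collapse clusters; record the effective count
    k = int(len(np.unique(labels)))
    return ClusterResult(
        k=k,
        labels=labels,
        region_names=profiles.region_names,
        inertia_curve=curve,
        seed=seed,
        n_init=n_init,
    )


def cluster_report(result: ClusterResult, profiles: CentralityProfileMatrix) -> pd.DataFrame:
    """Table of regions grouped by cluster, ordered for reading.

    Cluster ids are renumbered so cluster 1 has the highest mean Average;
    within a cluster rows are sorted by Average descending.  All downstream
    writers round at 4 decimals.
    """
    if result.region_names != profiles.region_names:
        raise ValidationError("cluster result and profile matrix cover different regions")
    df = profiles.to_frame()
    df.insert(0, "cluster", result.labels)
    order = (
        df.groupby("cluster")["average"].mean().sort_values(ascending=False).index
    )
    renumber = {old: new + 1 for new, old in enumerate(order)}
    df["cluster"] = df["cluster"].map(renumber)
    df = df.sort_values(["cluster", "average"], ascending=[True, False], kind="mergesort")
    return df.reset_index(drop=True)
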