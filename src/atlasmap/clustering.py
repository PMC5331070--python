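"""K-means partitioning of 3D neuron clouds with elbow selection.

The number of spatial clusters is chosen by scanning k and plotting the
percentage of variance explained, 100·(1 − WSS/TSS), where WSS is the
within-cluster sum of squared distances and TSS the total sum of squares
about the global centroid. The "elbow" — the k after which additional
clusters yield only marginal gains — is located reproducibly as the
interior point of the curve farthest from the chord joining its endpoints.

Lloyd iterations are delegated to scikit-learn; this module owns the
restart policy, a monotone warm-start chain across k (the best (k−1)
solution plus a split of its widest cluster always competes with fresh
restarts, which guarantees the variance curve is non-decreasing), and the
variance accounting. Distances are in voxel units: on an isotropic grid
this differs from µm by a global scale that cancels in the variance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .atlas_io import DEFAULT_VOXEL_SIZE_UM, point_array

_DEGENERATE_TSS = 1e-12


@dataclass
class ClusterModel:
    """Result of one k-means fit (cluster ids are 1-based)."""

    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    wss: float
    tss: float
    n_restarts: int
    seed: int
    degenerate: bool = False

    @property
    def pct_var(self) -> float:
        """Percentage of total variance explained by the partition.

        With zero total variance (all points identical) the partition is
        trivially perfect; reported as 100 with ``degenerate`` flagged.
        """
        if self.degenerate:
            return 100.0
        return 100.0 * (1.0 - self.wss / self.tss)


def _as_xyz(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return point_array(points)
    return np.asarray(points, dtype=float)


def _tss(X: np.ndarray) -> float:
    return float(((X - X.mean(axis=0)) ** 2).sum())


def kmeans_fit(points, k: int, n_restarts: int = 25, seed: int = 0) -> ClusterModel:
    """Best-of-restarts Lloyd k-means with squared-Euclidean distance.

    Deterministic given ``seed``. Raises for k < 1 or k > n points.
    """
    X = _as_xyz(points)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of points ({len(X)})")
    tss = _tss(X)
    if tss <= _DEGENERATE_TSS:
        return ClusterModel(
            k=k,
            assignments=np.ones(len(X), dtype=int),
            centroids=np.tile(X.mean(axis=0), (k, 1)),
            wss=0.0,
            tss=0.0,
            n_restarts=n_restarts,
            seed=seed,
            degenerate=True,
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    km.fit(X)
    return ClusterModel(
        k=k,
        assignments=km.labels_.astype(int) + 1,
        centroids=km.cluster_centers_.copy(),
        wss=float(km.inertia_),
        tss=tss,
        n_restarts=n_restarts,
        seed=seed,
    )


def _split_widest(X: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Warm-start centroid set for k+1: previous centroids plus a split.

    The widest cluster (largest within-cluster sum of squares) donates its
    farthest member as an additional centroid, so the warm start can only
    lower WSS relative to the k-cluster solution.
    """
    wss_per = np.zeros(model.k)
    far_point = np.zeros((model.k, X.shape[1]))
    for c in range(1, model.k + 1):
        members = X[model.assignments == c]
        if len(members) == 0:
            continue
        d2 = ((members - model.centroids[c - 1]) ** 2).sum(axis=1)
        wss_per[c - 1] = d2.sum()
        far_point[c - 1] = members[np.argmax(d2)]
    widest = int(np.argmax(wss_per))
    return np.vstack([model.centroids, far_point[widest]])


def elbow_scan(
    points,
    k_range: Iterable[int] = range(1, 21),
    n_restarts: int = 25,
    seed: int = 0,
) -> list[ClusterModel]:
    """Fit k-means over a range of k, keeping the variance curve monotone.

    For each k beyond the smallest, a warm start seeded from the previous
    best solution (split at its widest cluster) competes against
    ``n_restarts`` fresh random restarts; the lower-WSS model wins. Returns
    one ClusterModel per k, in order.
    """
    X = _as_xyz(points)
    ks = sorted(set(int(k) for k in k_range))
    models: list[ClusterModel] = []
    prev: ClusterModel | None = None
    for k in ks:
        best = kmeans_fit(X, k, n_restarts=n_restarts, seed=seed + k)
        if prev is not None and prev.k == k - 1 and not best.degenerate:
            init = _split_widest(X, prev)
            if len(np.unique(init, axis=0)) == k:
                km = KMeans(n_clusters=k, n_init=1, init=init, algorithm="lloyd")
                km.fit(X)
                if float(km.inertia_) < best.wss:
                    best = ClusterModel(
                        k=k,
                        assignments=km.labels_.astype(int) + 1,
                        centroids=km.cluster_centers_.copy(),
                        wss=float(km.inertia_),
                        tss=best.tss,
                        n_restarts=n_restarts,
                        seed=seed + k,
                    )
        models.append(best)
        prev = best
    return models


def variance_curve(models: Sequence[ClusterModel]) -> pd.DataFrame:
    """(k, pct_var, wss) table for a fitted scan."""
    return pd.DataFrame(
        {"k": [m.k for m in models],
         "pct_var": [m.pct_var for m in models],
         "wss": [m.wss for m in models]}
    )


def detect_elbow(curve) -> int:
    """Elbow of a (k, pct_var) curve by maximum chord distance.

    Accepts a DataFrame with k/pct_var columns or an (m, 2) array sorted by
    k. Returns the interior k whose point lies farthest from the straight
    chord joining the curve's endpoints; ties break toward smaller k. The
    published procedure located this turning point by eye; the chord rule is
    its deterministic surrogate.
    """
    if isinstance(curve, pd.DataFrame):
        arr = curve[["k", "pct_var"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("curve must contain at least 3 (k, pct_var) points")
    p0, p1 = arr[0], arr[-1]
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise ValueError("degenerate curve: identical endpoints")
    rel = arr - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    interior = dist[1:-1]
    best = int(np.argmax(interior)) + 1  # first (smallest-k) maximum wins ties
    return int(arr[best, 0])


def cluster_table(
    model: ClusterModel,
    points: pd.DataFrame,
    midline_x: float | None = None,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
) -> pd.DataFrame:
    """Per-cluster summary: size, centroid, laterality, per-animal makeup.

    Rows are sorted by descending cluster size. Centroids are given in voxel
    units and, when ``midline_x`` is supplied, as mm from the midline
    (negative = left).
    """
    if len(model.assignments) != len(points):
        raise ValueError("model was not fitted on this point table")
    animals = sorted(points["animal_id"].astype(str).unique())
    rows = []
    for c in range(1, model.k + 1):
        sel = model.assignments == c
        row: dict = {"cluster": c, "n": int(sel.sum())}
        cx, cy, cz = model.centroids[c - 1]
        row.update({"cx": cx, "cy": cy, "cz": cz})
        if midline_x is not None:
            row["lateral_mm"] = (cx - midline_x) * voxel_size_um / 1000.0
        sub = points.iloc[np.flatnonzero(sel)]
        for a in animals:
            row[f"n_{a}"] = int((sub["animal_id"].astype(str) == a).sum())
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values(["n", "cluster"], ascending=[False, True])
        .reset_index(drop=True)
    )


def assignments_export(model: ClusterModel, points: pd.DataFrame) -> pd.DataFrame:
    """Point table with the cluster id appended (coordinate-sheet layout)."""
    out = points.copy()
    out["cluster"] = model.assignments
    return out
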