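"""Second-level clustering of SOM prototypes.

The trained codebook (a few hundred prototype vectors) is partitioned by
k-means, and the number of clusters K is chosen by minimizing the
Davies-Bouldin index

    DB = (1/K) * sum_i max_{j != i} (d_i + d_j) / d(c_i, c_j)

where d_i is the average Euclidean distance of cluster i's members to its
centroid c_i and d(c_i, c_j) the centroid separation.  Lower DB means more
compact, better separated clusters.  Clustering operates in the same
normalized space used for SOM training so that cluster membership and BMU
assignment are consistent; every unit — including units that attract no
data — keeps a label, because the object being partitioned is the map.

Cluster labels are 1-based (cluster 1..K), matching the air-type numbering
used in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DataError, ValidationError


@dataclass
class Partition:
    """A k-means labeling of the prototypes."""

    k: int
    labels: np.ndarray            # per-unit cluster id in 1..k
    centroids: np.ndarray         # (k, n_channels)
    within_dispersion: np.ndarray  # per-cluster mean member-to-centroid distance
    sse: float                    # total within-cluster sum of squares
    restart_sse: list[float] = field(default_factory=list)

    @property
    def centroid_distances(self) -> np.ndarray:
        return cdist(self.centroids, self.centroids)

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]


@dataclass
class KSelection:
    k_range: list[int]
    db_index: list[float]
    best_k: int
    partitions: dict[int, Partition] = field(default_factory=dict)

    @property
    def best_partition(self) -> Partition:
        return self.partitions[self.best_k]


def _assign(points: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = cdist(points, centers)
    labels = np.argmin(d, axis=1)
    return labels, d[np.arange(len(points)), labels]


def _lloyd(points: np.ndarray, centers: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    k = len(centers)
    labels = np.full(len(points), -1)
    for _ in range(max_iter):
        new_labels, dist = _assign(points, centers)
        # empty-cluster repair: re-seed each empty cluster at the point
        # currently farthest from its assigned center
        for c in range(k):
            if not (new_labels == c).any():
                far = int(np.argmax(dist))
                centers[c] = points[far]
                new_labels[far] = c
                dist[far] = 0.0
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            m = labels == c
            if m.any():
                centers[c] = points[m].mean(axis=0)
    # final update so each centroid is exactly the mean of its members
    labels, _ = _assign(points, centers)
    for c in range(k):
        m = labels == c
        if m.any():
            centers[c] = points[m].mean(axis=0)
    sse = float(((points - centers[labels]) ** 2).sum())
    return labels, centers, sse


def kmeans(prototypes: np.ndarray, k: int, restarts: int = 10, seed=0,
           max_iter: int = 300) -> Partition:
    """Lloyd k-means over prototype vectors with multiple restarts.

    Each restart seeds from ``k`` distinct prototypes; the lowest-SSE run is
    returned (per-restart SSEs retained in ``restart_sse``).  Deterministic
    given ``seed``.
    """
    p = np.asarray(prototypes, dtype=float)
    if p.ndim != 2 or len(p) == 0:
        raise DataError("prototypes must be a nonempty 2-D matrix")
    if not 1 <= k <= len(p):
        raise ValidationError(f"k={k} outside [1, {len(p)}]")
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    trace: list[float] = []
    for _ in range(restarts):
        idx = rng.choice(len(p), size=k, replace=False)
        labels, centers, sse = _lloyd(p, p[idx].copy(), max_iter)
        trace.append(sse)
        if best is None or sse < best[2]:
            best = (labels, centers, sse)
    labels, centers, sse = best
    disp = np.array([
        np.linalg.norm(p[labels == c] - centers[c], axis=1).mean()
        for c in range(k)
    ])
    return Partition(
        k=k, labels=labels + 1, centroids=centers,
        within_dispersion=disp, sse=sse, restart_sse=trace,
    )


def partition_from_labels(prototypes: np.ndarray, labels: np.ndarray) -> Partition:
    """Rebuild a full :class:`Partition` (centroids, dispersions, SSE) from
    stored 1-based labels, e.g. when reloading a partition CSV."""
    p = np.asarray(prototypes, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if len(lab) != len(p):
        raise DataError("labels length does not match prototypes")
    k = int(lab.max())
    if lab.min() < 1:
        raise DataError("labels must be 1-based cluster ids")
    centers = np.empty((k, p.shape[1]))
    disp = np.empty(k)
    for c in range(k):
        m = lab == c + 1
        if not m.any():
            raise DataError(f"cluster {c + 1} is empty")
        centers[c] = p[m].mean(axis=0)
        disp[c] = np.linalg.norm(p[m] - centers[c], axis=1).mean()
    sse = float(((p - centers[lab - 1]) ** 2).sum())
    return Partition(k=k, labels=lab, centroids=centers,
                     within_dispersion=disp, sse=sse)


def davies_bouldin(prototypes: np.ndarray, partition: Partition) -> float:
    """Davies-Bouldin index of a partition (see module docstring).

    Requires k >= 2, no empty cluster, and distinct centroids (the ratio is
    undefined for coincident centroids).
    """
    p = np.asarray(prototypes, dtype=float)
    k = partition.k
    if k < 2:
        raise ValidationError("Davies-Bouldin requires k >= 2")
    d_i = np.empty(k)
    for c in range(k):
        m = partition.labels == c + 1
        if not m.any():
            raise DataError(f"cluster {c + 1} is empty")
        d_i[c] = np.linalg.norm(p[m] - partition.centroids[c], axis=1).mean()
    sep = cdist(partition.centroids, partition.centroids)
    off = ~np.eye(k, dtype=bool)
    if (sep[off] == 0).any():
        raise DataError("coincident centroids: Davies-Bouldin undefined")
    ratio = (d_i[:, None] + d_i[None, :]) / np.where(off, sep, np.inf)
    return float(ratio.max(axis=1).mean())


def select_k(prototypes: np.ndarray, k_min: int = 2, k_max: int = 8,
             restarts: int = 10, seed=0) -> KSelection:
    """Run k-means for each candidate K and pick the Davies-Bouldin argmin
    (ties broken toward smaller K).  The full per-K table is retained for
    diagnostics."""
    p = np.asarray(prototypes, dtype=float)
    if not 2 <= k_min <= k_max <= len(p):
        raise ValidationError(f"need 2 <= k_min <= k_max <= {len(p)}")
    k_range = list(range(k_min, k_max + 1))
    db: list[float] = []
    parts: dict[int, Partition] = {}
    for k in k_range:
        part = kmeans(p, k, restarts=restarts, seed=[_seed_int(seed), k])
        parts[k] = part
        db.append(davies_bouldin(p, part))
    best_k = k_range[int(np.argmin(db))]
    return KSelection(k_range=k_range, db_index=db, best_k=best_k, partitions=parts)


def _seed_int(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    raise ValidationError("seed must be an integer")


def cluster_variance(prototypes: np.ndarray, partition: Partition,
                     norm=None) -> np.ndarray:
    """Per-cluster total variance: sum over channels of the population
    variance (ddof=0) of the member prototypes' weights — i.e. the trace of
    the member covariance matrix.  If ``norm`` is given, variances are
    computed on denormalized weights (original ratio units)."""
    p = np.asarray(prototypes, dtype=float)
    if norm is not None:
        from .som import normalize_invert

        p = normalize_invert(norm, p)
    out = np.empty(partition.k)
    for c in range(partition.k):
        m = partition.labels == c + 1
        if not m.any():
            raise DataError(f"cluster {c + 1} is empty")
        out[c] = p[m].var(axis=0, ddof=0).sum()
    return out
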