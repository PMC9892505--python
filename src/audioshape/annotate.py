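"""Unsupervised shape annotation: spectral clustering with internal validation.

Audiograms are clustered by the similarity of their level vectors.  The
clustering is the classic normalized-spectral-embedding recipe:

1. Gaussian affinity with self-tuning local bandwidths,
   w(i, j) = exp(−‖hᵢ − hⱼ‖² / σᵢσⱼ) where σᵢ is the distance from point i
   to its 7th nearest neighbour (a single global σ — the median pairwise
   distance, available as ``sigma="median"`` — is too flat when cluster
   scales differ and merges adjacent severity groups);
2. sparsified to a symmetrized k-nearest-neighbour graph (10 neighbours by
   default);
3. the k leading eigenvectors of the symmetric normalized adjacency
   D^{−1/2} W D^{−1/2} form the embedding, rows normalized to unit length;
4. seeded k-means on the embedding yields the labels (1-based).

Model selection over a candidate range of k uses three internal criteria —
silhouette (higher better), Calinski–Harabasz (higher better) and
Davies–Bouldin (lower better).  By default the criteria are evaluated in the
spectral embedding, the space k-means actually partitions: there a correct k
produces near-orthogonal cluster indicators and a sharp silhouette peak,
whereas in raw level space adjacent severity clusters sit close together and
the criteria reward merging them.  ``criteria_space="levels"`` evaluates
them on the raw thresholds instead.
Weakly clustered audiograms (per-sample silhouette below a threshold) can be
removed afterwards, and audiograms representing normal hearing (every
threshold at or below a cutoff, default 20 dB HL) are dropped before
clustering since the pipeline targets hearing-loss shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_samples,
    silhouette_score,
)

from audioshape.core import Audiogram

__all__ = [
    "ClusteringResult",
    "spectral_cluster",
    "choose_k",
    "clean_weak_members",
    "drop_normal_hearing",
]

DEFAULT_N_NEIGHBORS = 10


@dataclass
class ClusteringResult:
    """Labels and internal-validity criteria of one clustering."""

    k: int
    labels: np.ndarray  # 1-based class ids aligned to the input order
    criteria: Dict[str, float]
    removed_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise ValueError("labels must lie in 1..k")


def _levels_matrix(data: Sequence[Audiogram]) -> np.ndarray:
    return np.vstack([a.levels for a in data])


def _criteria(x: np.ndarray, labels: np.ndarray) -> Dict[str, float]:
    if len(set(labels.tolist())) < 2:
        return {"silhouette": float("nan"), "calinski_harabasz": float("nan"),
                "davies_bouldin": float("nan")}
    return {
        "silhouette": float(silhouette_score(x, labels)),
        "calinski_harabasz": float(calinski_harabasz_score(x, labels)),
        "davies_bouldin": float(davies_bouldin_score(x, labels)),
    }


LOCAL_SCALE_NEIGHBOR = 7  # self-tuning bandwidth: distance to this neighbour


def spectral_embedding(
    x: np.ndarray,
    k: int,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    sigma: str = "local",
) -> np.ndarray:
    """Row-normalized k-dimensional spectral embedding of the points."""
    n = x.shape[0]
    dist = squareform(pdist(x))
    if sigma == "local":
        kth = min(LOCAL_SCALE_NEIGHBOR, n - 1)
        scale = np.sort(dist, axis=1)[:, kth]
        if np.all(scale == 0.0):
            raise ValueError("all points identical: zero local scale")
        scale[scale == 0.0] = scale[scale > 0.0].min()
        w = np.exp(-(dist**2) / (scale[:, None] * scale[None, :]))
    elif sigma == "median":
        s = float(np.median(dist[np.triu_indices(n, k=1)]))
        if s == 0.0:
            raise ValueError("all points identical: zero median pairwise distance")
        w = np.exp(-(dist**2) / (2.0 * s**2))
    else:
        raise ValueError("sigma must be 'local' or 'median'")
    np.fill_diagonal(w, 0.0)

    # symmetrized kNN graph: keep an edge if either endpoint ranks it
    nn = min(n_neighbors, n - 1)
    keep = np.zeros_like(w, dtype=bool)
    order = np.argsort(-w, axis=1)
    rows = np.repeat(np.arange(n), nn)
    keep[rows, order[:, :nn].ravel()] = True
    keep |= keep.T
    w = np.where(keep, w, 0.0)

    deg = w.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("isolated point in the affinity graph; increase n_neighbors")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    m = w * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    eigvals, eigvecs = np.linalg.eigh(m)
    u = eigvecs[:, -k:]  # k leading eigenvectors of the normalized adjacency
    norms = np.linalg.norm(u, axis=1)
    norms[norms == 0] = 1.0
    return u / norms[:, None]


def spectral_cluster(
    data: Sequence[Audiogram],
    k: int,
    seed: int = 0,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    criteria_space: str = "embedding",
) -> ClusteringResult:
    """Cluster audiograms into k shape classes; deterministic given seed."""
    n = len(data)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of audiograms n = {n}")
    if criteria_space not in ("embedding", "levels"):
        raise ValueError("criteria_space must be 'embedding' or 'levels'")
    x = _levels_matrix(data)
    u = spectral_embedding(x, k, n_neighbors=n_neighbors)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(u) + 1  # 1-based class ids
    space = u if criteria_space == "embedding" else x
    return ClusteringResult(k=k, labels=labels, criteria=_criteria(space, labels))


def choose_k(
    data: Sequence[Audiogram],
    k_range: Sequence[int],
    seed: int = 0,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    criteria_space: str = "embedding",
) -> int:
    """Pick the k whose clustering scores best across the three criteria.

    Each candidate k is ranked on silhouette (descending), Calinski–Harabasz
    (descending) and Davies–Bouldin (ascending).  The winner is the k that
    gives the highest (best) value on the most criteria; ties are broken by
    mean rank across the criteria, then by the smaller k.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    n = len(data)
    bad = [k for k in ks if not 2 <= k <= n - 1]
    if bad:
        raise ValueError(f"k values {bad} outside the valid range [2, {n - 1}]")
    if len(ks) == 1:
        return ks[0]
    results = {
        k: spectral_cluster(data, k, seed=seed, n_neighbors=n_neighbors,
                            criteria_space=criteria_space)
        for k in ks
    }
    si = np.array([results[k].criteria["silhouette"] for k in ks])
    ch = np.array([results[k].criteria["calinski_harabasz"] for k in ks])
    db = np.array([results[k].criteria["davies_bouldin"] for k in ks])

    def ranks(values: np.ndarray, higher_better: bool) -> np.ndarray:
        order = -values if higher_better else values
        # average rank of ties so the aggregate is order-independent
        return rankdata(order, method="average")

    rank_matrix = np.vstack([ranks(si, True), ranks(ch, True), ranks(db, False)])
    first_places = (rank_matrix == 1.0).sum(axis=0)
    mean_rank = rank_matrix.mean(axis=0)
    best = int(np.lexsort((ks, mean_rank, -first_places))[0])
    return ks[best]


def clean_weak_members(
    result: ClusteringResult,
    data: Sequence[Audiogram],
    threshold: float = 0.1,
) -> ClusteringResult:
    """Drop audiograms whose per-sample silhouette falls below the threshold.

    Criteria are recomputed on the survivors with their existing labels.
    Returns a result whose ``removed_ids`` lists the dropped audiograms (by
    id); ``labels`` is aligned to the surviving audiograms in input order.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("silhouette threshold must lie in [-1, 1]")
    x = _levels_matrix(data)
    if len(data) != result.labels.size:
        raise ValueError("result labels not aligned to data")
    per_sample = silhouette_samples(x, result.labels)
    keep = per_sample >= threshold
    removed = [data[i].id for i in np.flatnonzero(~keep)]
    survivors_x = x[keep]
    survivors_labels = result.labels[keep]
    return ClusteringResult(
        k=result.k,
        labels=survivors_labels,
        criteria=_criteria(survivors_x, survivors_labels),
        removed_ids=list(result.removed_ids) + removed,
    )


def drop_normal_hearing(
    data: Sequence[Audiogram],
    cutoff_db: float = 20.0,
) -> list:
    """Remove audiograms whose every threshold is at or below the cutoff.

    Such audiograms represent normal hearing and carry no hearing-loss shape
    to classify.
    """
    return [a for a in data if np.any(a.levels > cutoff_db)]
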