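"""Single-platform clustering baselines and cluster-quality machinery.

K-means with silhouette-based model selection, agglomerative clustering
under euclidean / cosine / Spearman-correlation distances, entropy-based
feature ranking, and partition-agreement metrics (adjusted Rand index
and best-label-matching agreement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .containers import SubtypeAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringRun",
    "kmeans_select_k",
    "hierarchical_cluster",
    "entropy_rank_features",
    "cluster_concordance",
]


@dataclass
class ClusteringRun:
    labels: SubtypeAssignment
    k: int
    mean_silhouette: float
    method: str
    metric: str
    linkage: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.mean_silhouette <= 1.0:
            raise ValueError("silhouette out of [-1, 1]")
        if self.labels.n_clusters != self.k:
            raise ValueError(
                f"{self.labels.n_clusters} distinct labels but k={self.k}"
            )


def _ids_or_default(sample_ids, n: int) -> list[str]:
    return list(sample_ids) if sample_ids is not None else [f"S{i:03d}" for i in range(n)]


def kmeans_select_k(
    X: np.ndarray,
    k_values=(2, 3, 4, 5),
    replicates: int = 500,
    seed: int = 0,
    sample_ids=None,
    silhouette_metric: str = "euclidean",
) -> ClusteringRun:
    """Best-silhouette k-means over a grid of cluster counts.

    For each k the best of ``replicates`` random restarts (by inertia)
    is kept, and the run with the highest mean silhouette wins.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if min(k_values) < 2:
        raise ValueError("k=1 rejected: silhouette is undefined")
    if max(k_values) >= n:
        raise ValueError(f"max k ({max(k_values)}) must be < n_samples ({n})")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all samples identical (zero variance)")

    best: ClusteringRun | None = None
    ids = _ids_or_default(sample_ids, n)
    for k in sorted(k_values):
        km = KMeans(n_clusters=k, n_init=replicates, max_iter=300, random_state=seed)
        labels = km.fit_predict(X) + 1
        sil = float(silhouette_score(X, labels, metric=silhouette_metric))
        run = ClusteringRun(
            labels=SubtypeAssignment(sample_ids=ids, labels=labels),
            k=k,
            mean_silhouette=sil,
            method="kmeans",
            metric=silhouette_metric,
        )
        if best is None or run.mean_silhouette > best.mean_silhouette:
            best = run
    assert best is not None
    return best


def _profile_distances(X: np.ndarray, metric: str, sample_ids: list[str]) -> np.ndarray:
    """Condensed pairwise distances between sample profiles."""
    if metric == "euclidean":
        return pdist(X, metric="euclidean")
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            bad = sample_ids[int(np.argmin(norms))]
            raise ValueError(f"sample {bad!r} has a zero profile: cosine distance undefined")
        return pdist(X, metric="cosine")
    if metric == "spearman":
        ranks = rankdata(X, axis=1)
        sds = ranks.std(axis=1)
        if np.any(sds == 0):
            bad = sample_ids[int(np.argmin(sds))]
            raise ValueError(
                f"sample {bad!r} has a constant profile: rank correlation undefined"
            )
        return pdist(ranks, metric="correlation")
    raise ValueError(f"unsupported metric {metric!r}")


def hierarchical_cluster(
    X: np.ndarray,
    metric: str = "cosine",
    linkage_method: str = "complete",
    k: int = 2,
    sample_ids=None,
) -> ClusteringRun:
    """Agglomerative clustering of sample profiles, cut into k clusters.

    Spearman distance is 1 minus the rank correlation between sample
    profiles.  Deterministic (no randomness in the tree or the cut).
    """
    X = np.asarray(X, dtype=float)
    ids = _ids_or_default(sample_ids, X.shape[0])
    d = _profile_distances(X, metric, ids)
    Z = linkage(d, method=linkage_method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    sil = float(silhouette_score(squareform(d), labels, metric="precomputed"))
    return ClusteringRun(
        labels=SubtypeAssignment(sample_ids=ids, labels=labels),
        k=int(np.unique(labels).size),
        mean_silhouette=sil,
        method="hierarchical",
        metric=metric,
        linkage=linkage_method,
    )


def entropy_rank_features(
    X: np.ndarray, n_top: int, n_bins: int = 10, feature_ids=None
) -> list[str]:
    """Features ranked by Shannon entropy of their across-sample histogram.

    Each feature is binned into ``n_bins`` equal-width bins over its own
    observed range, making the ranking invariant to per-feature affine
    rescaling.  Constant features get entropy 0 and rank last; ties
    break by feature id.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if n_top > p:
        raise ValueError(f"n_top ({n_top}) exceeds n_features ({p})")
    fids = list(feature_ids) if feature_ids is not None else [f"f{j:04d}" for j in range(p)]
    ent = np.zeros(p)
    for j in range(p):
        col = X[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0 or col.max() == col.min():
            continue
        counts, _ = np.histogram(col, bins=n_bins, range=(col.min(), col.max()))
        q = counts[counts > 0] / counts.sum()
        ent[j] = float(-(q * np.log2(q)).sum())
    order = sorted(range(p), key=lambda j: (-ent[j], fids[j]))
    return [fids[j] for j in order[:n_top]]


def cluster_concordance(
    a: SubtypeAssignment, b: SubtypeAssignment
) -> tuple[float, float]:
    """(adjusted Rand index, best-label-matching agreement) of two partitions.

    Agreement is the maximal fraction of samples with equal labels under
    the optimal label bijection (Hungarian matching on the contingency
    table); it is what "the two classifiers agreed on x% of patients"
    measures.
    """
    if set(a.sample_ids) != set(b.sample_ids):
        raise ValueError("partitions cover different sample sets")
    order = {s: i for i, s in enumerate(a.sample_ids)}
    b_labels = np.empty(len(a.sample_ids), dtype=object)
    for s, lab in zip(b.sample_ids, b.labels):
        b_labels[order[s]] = lab
    la = np.asarray(a.labels)
    lb = np.asarray(b_labels)

    ari = float(adjusted_rand_score(la, lb))
    ua, ub = np.unique(la), np.unique(lb)
    cont = np.zeros((ua.size, ub.size))
    for i, va in enumerate(ua):
        for j, vb in enumerate(ub):
            cont[i, j] = np.sum((la == va) & (lb == vb))
    rows, cols = linear_sum_assignment(-cont)
    agreement = float(cont[rows, cols].sum() / la.size)
    return ari, agreement
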