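"""Similarity network fusion and spectral clustering.

Each molecular layer is turned into a patient similarity network with a
locally adaptive Gaussian kernel; the per-layer networks are fused by
iterative cross-diffusion (each layer's global status matrix is diffused
through the other layers' local K-nearest-neighbour kernels), and the
fused network is clustered with normalized-Laplacian spectral clustering.
The number of clusters can be chosen with the eigengap heuristic.

Kernel and normalization conventions
------------------------------------
* affinity   W(i,j) = exp(−d²(i,j) / (alpha · eps(i,j))) with
  eps(i,j) = (mu_i + mu_j + d(i,j)) / 3, mu_i the mean distance from i
  to its K nearest neighbours, d Euclidean on standardized features.
* status     P(i,j) = W(i,j) / (2 Σ_{k≠i} W(i,k)) off-diagonal, P(i,i)=1/2.
* local      S(i,j) = W(i,j) / Σ_{k∈N_i} W(i,k) for j in the K-NN set of
  i (self excluded), else 0.
* fusion     P_v ← S_v · mean_{w≠v}(P_w) · S_vᵀ, then symmetrize and
  re-normalize rows, for t iterations; the fused network is the
  symmetrized mean of the final status matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

from .containers import AffinityNetwork, OmicsLayer, SubtypeAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "SNFParams",
    "standardize_layer",
    "affinity_from_layer",
    "status_and_local",
    "fuse",
    "spectral_cluster",
    "estimate_k_eigengap",
    "snf_cluster",
]


@dataclass(frozen=True)
class SNFParams:
    """Fusion hyperparameters: K nearest neighbours, kernel bandwidth
    multiplier alpha, and diffusion iterations t.

    Defaults follow common practice for cohorts of a few dozen samples:
    K=24 neighbours, alpha=0.7, t=25 iterations.  alpha in [0.3, 0.8]
    is the recommended range; any positive value is accepted.
    """

    n_neighbors: int = 24
    alpha: float = 0.7
    iterations: int = 25

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def standardize_layer(layer: OmicsLayer) -> OmicsLayer:
    """Mean-impute missing values and z-score each feature.

    Zero-variance features are dropped with a warning (they carry no
    distance information and would divide by zero).
    """
    X = layer.values.copy()
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        logger.warning("layer %s: mean-imputing %d missing values", layer.name, n_missing)
        col_mean = np.nanmean(X, axis=0)
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
    sd = X.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = [f for f, k in zip(layer.feature_ids, keep) if not k]
        logger.warning(
            "layer %s: dropping %d zero-variance features (e.g. %s)",
            layer.name,
            len(dropped),
            dropped[:3],
        )
        X = X[:, keep]
        if X.shape[1] == 0:
            raise ValueError(f"layer {layer.name}: all features have zero variance")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return OmicsLayer(
        name=layer.name,
        sample_ids=list(layer.sample_ids),
        feature_ids=[f for f, k in zip(layer.feature_ids, keep) if k],
        values=X,
    )


def affinity_from_layer(
    layer: OmicsLayer, params: SNFParams | None = None, assume_standardized: bool = False
) -> AffinityNetwork:
    """Locally scaled Gaussian affinity network from one layer.

    The bandwidth for each pair adapts to the local density:
    eps(i,j) averages the two samples' mean K-NN distances and their own
    distance, so dense and sparse regions of the cohort are treated
    comparably.
    """
    params = params or SNFParams()
    if not assume_standardized:
        layer = standardize_layer(layer)
    n = layer.n_samples
    K = params.n_neighbors
    if n < K + 1:
        raise ValueError(f"need n_samples >= K+1 ({K + 1}), got {n}")
    d = squareform(pdist(layer.values, metric="euclidean"))
    if np.all(d == 0):
        raise ValueError("all samples identical: zero kernel bandwidth")
    # mean distance from each sample to its K nearest neighbours (self excluded)
    d_sorted = np.sort(d, axis=1)[:, 1 : K + 1]
    mu = d_sorted.mean(axis=1)
    eps = (mu[:, None] + mu[None, :] + d) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, d**2 / (params.alpha * eps), 0.0)
    W = np.exp(-ratio)
    W = (W + W.T) / 2.0
    return AffinityNetwork(sample_ids=list(layer.sample_ids), W=W)


def status_and_local(network: AffinityNetwork, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Global status matrix P and local K-NN kernel S of one network.

    Every row of P and of S sums to one.  Samples with no off-diagonal
    affinity are reported by name (the normalizations are undefined).
    """
    W = network.W
    n = W.shape[0]
    if not 1 <= K <= n - 1:
        raise ValueError(f"K must be in [1, {n - 1}], got {K}")
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    if np.any(row <= 0):
        bad = network.sample_ids[int(np.argmin(row))]
        raise ValueError(f"isolated sample {bad!r}: zero off-diagonal affinity")
    P = off / (2.0 * row[:, None])
    np.fill_diagonal(P, 0.5)

    # K largest-affinity neighbours per row, self excluded
    S = np.zeros_like(W)
    for i in range(n):
        order = np.argsort(-off[i], kind="stable")[:K]
        S[i, order] = off[i, order]
    s_row = S.sum(axis=1)
    if np.any(s_row <= 0):
        bad = network.sample_ids[int(np.argmin(s_row))]
        raise ValueError(f"isolated sample {bad!r}: empty neighbour affinity")
    S /= s_row[:, None]
    return P, S


def _status_normalize(P: np.ndarray) -> np.ndarray:
    off = P.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    row = np.where(row > 0, row, 1.0)
    out = off / (2.0 * row[:, None])
    np.fill_diagonal(out, 0.5)
    return out


def fuse(
    layers_PS: list[tuple[np.ndarray, np.ndarray]],
    t: int = 25,
    sample_ids: list[str] | None = None,
) -> AffinityNetwork:
    """Cross-diffusion fusion of per-layer (P, S) pairs.

    All layers are updated simultaneously from the previous iteration's
    status matrices; after each update every status matrix is
    symmetrized and row-renormalized (asserted).  The fused network is
    the symmetrized mean of the final status matrices.
    """
    if len(layers_PS) < 2:
        raise ValueError("fusion needs at least two layers")
    n = layers_PS[0][0].shape[0]
    for P, S in layers_PS:
        if P.shape != (n, n) or S.shape != (n, n):
            raise ValueError("inconsistent matrix sizes across layers")
    Ps = [P.copy() for P, _ in layers_PS]
    Ss = [S for _, S in layers_PS]
    V = len(Ps)
    for _ in range(t):
        total = np.sum(Ps, axis=0)
        new_Ps = []
        for v in range(V):
            others = (total - Ps[v]) / (V - 1)
            P_v = Ss[v] @ others @ Ss[v].T
            P_v = (P_v + P_v.T) / 2.0
            assert np.allclose(P_v, P_v.T), "fusion step lost symmetry"
            P_v = _status_normalize(P_v)
            assert np.allclose(P_v.sum(axis=1), 1.0, atol=1e-8), "fusion step lost row normalization"
            new_Ps.append(P_v)
        Ps = new_Ps
    fused = np.mean(Ps, axis=0)
    fused = (fused + fused.T) / 2.0
    ids = sample_ids if sample_ids is not None else [f"S{i:03d}" for i in range(n)]
    return AffinityNetwork(sample_ids=ids, W=fused)


def fuse_layers(
    layers: list[OmicsLayer], params: SNFParams | None = None
) -> AffinityNetwork:
    """Convenience: affinity → (P, S) → fused network for a list of layers."""
    params = params or SNFParams()
    ids = layers[0].sample_ids
    for lay in layers[1:]:
        if lay.sample_ids != ids:
            raise ValueError(
                f"sample order mismatch between layers {layers[0].name!r} and {lay.name!r}"
            )
    pairs = []
    for lay in layers:
        net = affinity_from_layer(lay, params)
        pairs.append(status_and_local(net, params.n_neighbors))
    return fuse(pairs, t=params.iterations, sample_ids=list(ids))


def _normalized_laplacian(W: np.ndarray) -> np.ndarray:
    # self-loops carry no grouping information but can dwarf the
    # off-diagonal structure of sharply decaying kernels, so they are
    # dropped before normalization
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("network has a zero-degree (isolated) sample")
    inv_sqrt = 1.0 / np.sqrt(deg)
    return np.eye(W.shape[0]) - inv_sqrt[:, None] * W * inv_sqrt[None, :]


def spectral_cluster(network: AffinityNetwork, k: int, seed: int = 0) -> SubtypeAssignment:
    """Normalized-Laplacian spectral clustering of an affinity network.

    k-means (100 restarts, fixed seed) on the row-normalized top-k
    eigenvectors of L = I − D^{−1/2} W D^{−1/2}.  A disconnected network
    is clustered as-is (its components separate exactly in eigenspace)
    with a warning.
    """
    n = network.n_samples
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k ({k}) exceeds number of samples ({n})")
    n_comp, _ = connected_components((network.W > 0).astype(int), directed=False)
    if n_comp > 1:
        logger.warning("network has %d connected components", n_comp)
    L = _normalized_laplacian(network.W)
    _, vecs = eigh(L, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    U = vecs / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=k, n_init=100, random_state=seed)
    labels = km.fit_predict(U) + 1
    return SubtypeAssignment(sample_ids=list(network.sample_ids), labels=labels)


def estimate_k_eigengap(
    network: AffinityNetwork, k_max: int = 5, gap_floor: float = 0.05
) -> int:
    """Number of clusters by the eigengap heuristic.

    Returns the k in {2..k_max} maximizing λ_{k+1} − λ_k over the
    ascending eigenvalues of the normalized Laplacian.  Ties go to the
    smaller k; a best gap below ``gap_floor`` is flagged as weak (the
    network may have no cluster structure).
    """
    n = network.n_samples
    if not 2 <= k_max < n:
        raise ValueError(f"k_max must be in [2, {n - 1}]")
    lam = eigh(_normalized_laplacian(network.W), eigvals_only=True)
    gaps = {k: lam[k] - lam[k - 1] for k in range(2, k_max + 1)}
    best_gap = max(gaps.values())
    best_k = min(k for k, g in gaps.items() if g == best_gap)
    if sum(1 for g in gaps.values() if g == best_gap) > 1:
        logger.info("eigengap tie at %.3g broken toward k=%d", best_gap, best_k)
    if best_gap < gap_floor:
        logger.warning(
            "weak eigengap (%.3g < %.3g): cluster structure is doubtful", best_gap, gap_floor
        )
    return best_k


def snf_cluster(
    layers: list[OmicsLayer],
    params: SNFParams | None = None,
    k: int | None = None,
    k_max: int = 5,
    seed: int = 0,
) -> tuple[AffinityNetwork, SubtypeAssignment, int]:
    """Full fusion pipeline: fuse layers, pick k (eigengap) if not given,
    spectral-cluster the fused network."""
    fused = fuse_layers(layers, params)
    if k is None:
        k = estimate_k_eigengap(fused, k_max=k_max)
    return fused, spectral_cluster(fused, k, seed=seed), k
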