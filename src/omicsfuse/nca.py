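"""Regularized diagonal neighbourhood component analysis (NCA).

The diagonal adaptation of NCA learns one weight per feature by
maximizing a soft leave-one-out nearest-neighbour classification
objective.  With stochastic neighbour probabilities

    p_ij = exp(−d_w(i,j)) / Σ_{k≠i} exp(−d_w(i,k)),      p_ii = 0,

and the weighted-L1 distance d_w(i,j) = Σ_r w_r² |x_ir − x_jr|, the
objective is

    F(w) = (1/n) Σ_i Σ_{j : y_j = y_i} p_ij  −  λ Σ_r w_r².

The optimization variable w is unconstrained; the *effective*
per-feature weights are w_r² ≥ 0 and those are what the returned panel
reports.  The penalty drives the weights of uninformative features to
zero, which is what makes the fitted weight vector a feature-selection
device.

Optimization is deterministic full-batch gradient ascent with a
backtracking line search (the objective trace is non-decreasing), so
repeated fits on the same input are bit-identical.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import BiomarkerPanel

logger = logging.getLogger(__name__)

__all__ = [
    "fit_nca_weights",
    "soft_loo_accuracy",
    "select_panel",
    "minimal_panel_search",
]


def _pairwise_abs_diffs(X: np.ndarray) -> np.ndarray:
    """|x_ir − x_jr| flattened to shape (n*n, p).  Desk-scale cohorts
    (n of tens, p of thousands) keep this comfortably in memory."""
    n, p = X.shape
    D = np.abs(X[:, None, :] - X[None, :, :])
    return D.reshape(n * n, p)


def _soft_probs(dist: np.ndarray, same: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic neighbour probabilities P (p_ii = 0) and per-sample
    soft leave-one-out accuracies p_i."""
    n = dist.shape[0]
    logits = -dist.copy()
    np.fill_diagonal(logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    expd = np.exp(logits)
    P = expd / expd.sum(axis=1, keepdims=True)
    p_i = (P * same).sum(axis=1)
    return P, p_i


def soft_loo_accuracy(X: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    """Mean soft leave-one-out accuracy (1/n) Σ_i Σ_{j∈class(i)} p_ij under
    the given *effective* (nonnegative) feature weights."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    D = _pairwise_abs_diffs(X)
    dist = (D @ np.asarray(weights, dtype=float)).reshape(n, n)
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    _, p_i = _soft_probs(dist, same)
    return float(p_i.mean())


def fit_nca_weights(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    n_epochs: int = 200,
    init_step: float = 1.0,
    tol: float = 1e-8,
    feature_ids=None,
    layer_name: str = "other",
) -> BiomarkerPanel:
    """Fit diagonal NCA weights for one layer.

    Parameters
    ----------
    X
        Standardized (n_samples, n_features) matrix.
    y
        Class labels; at least two classes with two members each.
    lam
        Regularization strength on Σ_r w_r² (linear in the effective
        weights); default 1/n.
    n_epochs, init_step, tol
        Gradient-ascent budget, initial step size and relative
        convergence tolerance of the backtracking optimizer.

    Returns a :class:`BiomarkerPanel` whose ``weights`` are the learned
    effective weights w_r² and whose ``objective_trace`` records the
    (non-decreasing) objective after each accepted step.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if np.any(counts < 2):
        raise ValueError("every class needs at least two members")
    if lam is None:
        lam = 1.0 / n
    if lam < 0:
        raise ValueError("lambda must be >= 0")

    D = _pairwise_abs_diffs(X)  # (n*n, p)
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    # uniform init scaled so the mean pairwise distance is ~1: keeps the
    # softmax informative even for very high-dimensional layers
    mean_total = float(D.sum(axis=1).mean())
    if mean_total <= 0:
        raise ValueError("all samples identical: NCA distances degenerate")
    w = np.full(p, np.sqrt(1.0 / mean_total))

    def objective_and_grad(w_vec: np.ndarray) -> tuple[float, np.ndarray]:
        eff = w_vec**2
        dist = (D @ eff).reshape(n, n)
        P, p_i = _soft_probs(dist, same)
        F = float(p_i.mean()) - lam * float(eff.sum())
        # dF/dw_r = 2 w_r [ (1/n) Σ_{i,m} p_im (p_i − same_im) |x_ir − x_jr| − λ ]
        A = P * (p_i[:, None] - same)
        q = A.reshape(n * n) @ D
        grad = 2.0 * w_vec * (q / n - lam)
        return F, grad

    F, grad = objective_and_grad(w)
    trace = [F]
    step = init_step
    for _ in range(n_epochs):
        improved = False
        for _ in range(40):
            w_new = w + step * grad
            F_new, grad_new = objective_and_grad(w_new)
            if F_new >= F:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        gain = F_new - F
        w, F, grad = w_new, F_new, grad_new
        trace.append(F)
        step *= 1.2
        if gain < tol * (1.0 + abs(F)):
            break

    fids = list(feature_ids) if feature_ids is not None else [f"f{j:04d}" for j in range(p)]
    return BiomarkerPanel(
        layer_name=layer_name,
        feature_ids=fids,
        weights=w**2,
        lam=float(lam),
        objective_trace=np.asarray(trace),
    )


def select_panel(
    panel: BiomarkerPanel,
    rule: str = "weight_threshold",
    top_n: int | None = None,
    threshold: float | None = None,
    threshold_frac: float = 0.02,
) -> BiomarkerPanel:
    """Pick the selected feature subset from learned weights.

    ``rule="top_n"`` keeps the ``top_n`` heaviest features (used to pin a
    panel to a fixed size); ``rule="weight_threshold"`` keeps every
    feature with weight above ``threshold`` (default 2% of the maximum
    weight).  Selected features come back ordered by descending weight,
    ties broken by feature id.
    """
    order = sorted(
        range(len(panel.feature_ids)),
        key=lambda j: (-panel.weights[j], panel.feature_ids[j]),
    )
    if rule == "top_n":
        if top_n is None or not 1 <= top_n <= len(panel.feature_ids):
            raise ValueError("top_n must be in [1, n_features]")
        chosen = order[:top_n]
    elif rule == "weight_threshold":
        if threshold is None:
            threshold = threshold_frac * float(panel.weights.max())
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        chosen = [j for j in order if panel.weights[j] >= threshold]
        if not chosen:
            raise ValueError(
                f"no feature passes weight threshold {threshold:.3g}; lower the threshold"
            )
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return BiomarkerPanel(
        layer_name=panel.layer_name,
        feature_ids=list(panel.feature_ids),
        weights=panel.weights.copy(),
        selected=[panel.feature_ids[j] for j in chosen],
        lam=panel.lam,
        objective_trace=panel.objective_trace,
    )


def minimal_panel_search(
    X: np.ndarray,
    y: np.ndarray,
    classifier_spec,
    sizes=tuple(range(3, 11)),
    folds: int = 5,
    seed: int = 0,
    lam: float | None = None,
    feature_ids=None,
    layer_name: str = "other",
) -> tuple[int, BiomarkerPanel, float]:
    """Smallest high-performing panel: for each candidate size s, evaluate
    the top-s NCA-weighted features by stratified CV loss of the given
    classifier; returns (best_size, panel, cv_loss) with ties going to
    the smaller size."""
    from .classify import cross_validate

    X = np.asarray(X, dtype=float)
    if max(sizes) > X.shape[1]:
        raise ValueError("largest candidate size exceeds the number of features")
    fitted = fit_nca_weights(
        X, y, lam=lam, feature_ids=feature_ids, layer_name=layer_name
    )
    order = sorted(
        range(len(fitted.feature_ids)),
        key=lambda j: (-fitted.weights[j], fitted.feature_ids[j]),
    )
    best_size, best_loss = None, np.inf
    for s in sorted(sizes):
        cols = order[:s]
        res = cross_validate(classifier_spec, X[:, cols], y, folds=folds, seed=seed)
        loss = 1.0 - res.accuracy
        if loss < best_loss:
            best_size, best_loss = s, loss
    assert best_size is not None
    panel = select_panel(fitted, rule="top_n", top_n=best_size)
    return best_size, panel, float(best_loss)
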