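"""Supervised subtype classifiers on biomarker panels.

Wraps KNN ("cubic" = Minkowski exponent 3), SVM ("quadratic" =
degree-2 polynomial kernel, or Gaussian) and bagged decision trees
behind a uniform spec, with stratified 5-fold cross-validation,
CV-loss-minimizing hyperparameter search, posterior-probability
predictions with a 0.7 low-confidence flag, and transfer of a trained
model to an external cohort (dropping panel features the cohort lacks).

All preprocessing (standardization, posterior calibration) is fitted
inside training folds only, so cross-validated accuracies carry no
information leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .clustering import cluster_concordance, hierarchical_cluster
from .containers import BiomarkerPanel, OmicsLayer, SubtypeAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "TrainedClassifier",
    "Prediction",
    "CVResult",
    "TransferResult",
    "LOW_CONFIDENCE_THRESHOLD",
    "is_low_confidence",
    "cross_validate",
    "tune_hyperparameters",
    "train",
    "predict",
    "cohort_transfer",
]

#: max-posterior below this flags a prediction as low-confidence
LOW_CONFIDENCE_THRESHOLD = 0.7


def is_low_confidence(posterior: np.ndarray, threshold: float = LOW_CONFIDENCE_THRESHOLD) -> bool:
    """True when the maximum posterior is strictly below the threshold."""
    return bool(np.max(posterior) < threshold)


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its hyperparameters.

    families: ``knn`` (n_neighbors, distance exponent p, vote weighting),
    ``svm`` (kernel ``quadratic-polynomial`` or ``gaussian``, box
    constraint C, kernel scale), ``bagged_trees`` (n_estimators,
    max_depth).
    """

    family: str
    hyperparams: dict = field(default_factory=dict)
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.family not in {"knn", "svm", "bagged_trees"}:
            raise ValueError(f"unknown family {self.family!r}")
        hp = self.hyperparams
        if self.family == "knn" and hp.get("n_neighbors", 1) < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.family == "svm" and hp.get("C", 1.0) <= 0:
            raise ValueError("box constraint must be > 0")


def cubic_knn_spec(n_neighbors: int = 10) -> ClassifierSpec:
    """Cubic KNN: Minkowski distance with exponent 3, uniform votes."""
    return ClassifierSpec("knn", {"n_neighbors": n_neighbors, "p": 3, "weights": "uniform"})


def quadratic_svm_spec(C: float = 1.0, scale: float = 1.0) -> ClassifierSpec:
    """Quadratic SVM: degree-2 polynomial kernel."""
    return ClassifierSpec("svm", {"kernel": "quadratic-polynomial", "C": C, "scale": scale})


def coarse_gaussian_svm_spec(C: float = 1.0, scale: float = 4.0) -> ClassifierSpec:
    """Gaussian SVM with a coarse (large) kernel scale."""
    return ClassifierSpec("svm", {"kernel": "gaussian", "C": C, "scale": scale})


def bagged_trees_spec(n_estimators: int = 30) -> ClassifierSpec:
    return ClassifierSpec("bagged_trees", {"n_estimators": n_estimators})


def _build_estimator(spec: ClassifierSpec, seed: int = 0):
    hp = spec.hyperparams
    if spec.family == "knn":
        est = KNeighborsClassifier(
            n_neighbors=hp.get("n_neighbors", 10),
            p=hp.get("p", 3),
            weights=hp.get("weights", "uniform"),
            metric="minkowski",
        )
    elif spec.family == "svm":
        kernel = hp.get("kernel", "quadratic-polynomial")
        scale = hp.get("scale", 1.0)
        gamma = 1.0 / (scale**2)
        if kernel == "quadratic-polynomial":
            base = SVC(kernel="poly", degree=2, coef0=1.0, gamma=gamma,
                       C=hp.get("C", 1.0), random_state=seed)
        elif kernel == "gaussian":
            base = SVC(kernel="rbf", gamma=gamma, C=hp.get("C", 1.0),
                       random_state=seed)
        else:
            raise ValueError(f"unknown svm kernel {kernel!r}")
        # posteriors via sigmoid (Platt) calibration on internal training folds
        est = CalibratedClassifierCV(base, method="sigmoid", cv=3, ensemble=False)
    else:  # bagged_trees
        est = BaggingClassifier(
            estimator=DecisionTreeClassifier(
                max_depth=hp.get("max_depth"), random_state=seed
            ),
            n_estimators=hp.get("n_estimators", 30),
            random_state=seed,
        )
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return Pipeline([("clf", est)])


@dataclass
class CVResult:
    accuracy: float
    auroc: float | None
    folds: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy out of [0,1]")


def cross_validate(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, folds: int = 5, seed: int = 0
) -> CVResult:
    """Stratified k-fold accuracy (and AUROC for two-class problems).

    The full pipeline — including standardization — is re-fitted inside
    each training fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < {folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    scores = np.empty(y.shape[0])
    for train_idx, test_idx in skf.split(X, y):
        est = _build_estimator(spec, seed=seed)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        correct += int(np.sum(pred == y[test_idx]))
        if classes.size == 2:
            proba = est.predict_proba(X[test_idx])
            pos_col = int(np.where(est.classes_ == classes[1])[0][0])
            scores[test_idx] = proba[:, pos_col]
    auroc = (
        float(roc_auc_score((y == classes[1]).astype(int), scores))
        if classes.size == 2
        else None
    )
    return CVResult(accuracy=correct / y.shape[0], auroc=auroc, folds=folds)


def _sample_spec(family: str, rng: np.random.Generator, n: int) -> ClassifierSpec:
    if family == "knn":
        return ClassifierSpec(
            "knn",
            {
                "n_neighbors": int(rng.integers(1, min(26, max(2, n - 1)))),
                "p": int(rng.choice([1, 2, 3])),
                "weights": str(rng.choice(["uniform", "distance"])),
            },
        )
    if family == "svm":
        return ClassifierSpec(
            "svm",
            {
                "kernel": str(rng.choice(["quadratic-polynomial", "gaussian"])),
                "C": float(10 ** rng.uniform(-2, 3)),
                "scale": float(10 ** rng.uniform(-1.5, 1.5)),
            },
        )
    if family == "bagged_trees":
        return ClassifierSpec(
            "bagged_trees",
            {
                "n_estimators": int(rng.integers(10, 101)),
                "max_depth": int(rng.integers(2, 11)),
            },
        )
    raise ValueError(f"unknown family {family!r}")


def tune_hyperparameters(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    budget: int = 60,
    seed: int = 0,
    folds: int = 5,
) -> tuple[ClassifierSpec, float]:
    """Minimize 5-fold CV loss over a family's hyperparameter space.

    Random search with log-uniform sampling for scale-like parameters;
    any strategy meeting the same minimize-CV-loss contract could be
    substituted.  Returns (best spec, its CV loss); the best loss never
    exceeds that of any spec evaluated within the budget.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    best_spec, best_loss = None, np.inf
    for _ in range(budget):
        spec = _sample_spec(family, rng, X.shape[0])
        loss = 1.0 - cross_validate(spec, X, y, folds=folds, seed=seed).accuracy
        if loss < best_loss:
            best_spec, best_loss = spec, loss
    assert best_spec is not None
    return best_spec, float(best_loss)


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    pipeline: object
    feature_ids: list[str]
    sample_ids: list[str]
    classes: np.ndarray
    cv_accuracy: float | None = None
    X_train: np.ndarray | None = None
    y_train: np.ndarray | None = None


@dataclass
class Prediction:
    sample_id: str
    label: object
    posterior: np.ndarray
    low_confidence: bool

    def __post_init__(self) -> None:
        self.posterior = np.asarray(self.posterior, dtype=float)
        if np.any(self.posterior < 0) or abs(self.posterior.sum() - 1.0) > 1e-9:
            raise ValueError("posterior must be nonnegative and sum to 1")


def train(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    feature_ids,
    sample_ids=None,
    seed: int = 0,
    cv_folds: int | None = 5,
) -> TrainedClassifier:
    """Fit a classifier on a biomarker matrix, recording CV accuracy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv_acc = (
        cross_validate(spec, X, y, folds=cv_folds, seed=seed).accuracy
        if cv_folds
        else None
    )
    pipe = _build_estimator(spec, seed=seed)
    pipe.fit(X, y)
    ids = list(sample_ids) if sample_ids is not None else [f"S{i:03d}" for i in range(X.shape[0])]
    return TrainedClassifier(
        spec=spec,
        pipeline=pipe,
        feature_ids=list(feature_ids),
        sample_ids=ids,
        classes=np.asarray(pipe.classes_),
        cv_accuracy=cv_acc,
        X_train=X,
        y_train=y,
    )


def predict(
    model: TrainedClassifier, X_new: np.ndarray, sample_ids, feature_ids
) -> list[Prediction]:
    """Posterior predictions for new samples, flagged below max-posterior 0.7.

    ``feature_ids`` must cover the model's training features (matched by
    id, reordered as needed); missing features are an error listing them.
    """
    feature_ids = list(feature_ids)
    missing = [f for f in model.feature_ids if f not in feature_ids]
    if missing:
        raise ValueError(f"query is missing model features: {missing}")
    cols = [feature_ids.index(f) for f in model.feature_ids]
    Xq = np.asarray(X_new, dtype=float)[:, cols]
    proba = model.pipeline.predict_proba(Xq)
    out = []
    for i, sid in enumerate(sample_ids):
        post = proba[i]
        label = model.classes[int(np.argmax(post))]
        out.append(
            Prediction(
                sample_id=str(sid),
                label=label,
                posterior=post,
                low_confidence=is_low_confidence(post),
            )
        )
    return out


@dataclass
class TransferResult:
    predictions: list[Prediction]
    predicted: SubtypeAssignment
    cluster_labels: SubtypeAssignment
    agreement: float
    n_features_used: int


def cohort_transfer(
    model: TrainedClassifier,
    external_layer: OmicsLayer,
    panel: BiomarkerPanel,
    min_fraction: float = 0.5,
    k: int = 2,
    seed: int = 0,
) -> TransferResult:
    """Transfer a trained panel classifier to an external cohort.

    Panel features absent from the external layer are dropped from both
    the model (which is re-fitted on the reduced panel) and the data,
    with a log message.  The external biomarker matrix is standard-
    normalized (its own statistics, to absorb platform shifts), the
    model predicts subtype labels, and the same matrix is independently
    clustered (hierarchical, cosine distance, complete linkage) so the
    supervised and unsupervised labelings can be compared by best-match
    agreement.
    """
    panel_feats = panel.selected if panel.selected else panel.feature_ids
    present = [f for f in panel_feats if f in external_layer.feature_ids]
    frac = len(present) / len(panel_feats)
    if frac < min_fraction:
        raise ValueError(
            f"only {len(present)}/{len(panel_feats)} panel features present "
            f"({frac:.0%} < {min_fraction:.0%})"
        )
    if model.X_train is None:
        raise ValueError("model lacks stored training data; cannot transfer")
    if len(present) < len(panel_feats):
        logger.warning(
            "re-fitting model on %d/%d panel features present in external cohort",
            len(present),
            len(panel_feats),
        )
    # both cohorts are taken to their own standard-normalized space so the
    # model sees platform-free coordinates on either side
    cols = [model.feature_ids.index(f) for f in present]
    Xt = model.X_train[:, cols]
    t_sd = np.where(Xt.std(axis=0) > 0, Xt.std(axis=0), 1.0)
    Xt = (Xt - Xt.mean(axis=0)) / t_sd
    used_model = train(
        model.spec,
        Xt,
        model.y_train,
        feature_ids=present,
        sample_ids=model.sample_ids,
        seed=seed,
        cv_folds=None,
    )

    ext_cols = [external_layer.feature_ids.index(f) for f in present]
    Xe = external_layer.values[:, ext_cols]
    sd = Xe.std(axis=0)
    if np.any(sd == 0):
        sd = np.where(sd > 0, sd, 1.0)
    Xe = (Xe - Xe.mean(axis=0)) / sd

    preds = predict(used_model, Xe, external_layer.sample_ids, present)
    predicted = SubtypeAssignment(
        sample_ids=list(external_layer.sample_ids),
        labels=np.array([p.label for p in preds]),
    )
    run = hierarchical_cluster(
        Xe, metric="cosine", linkage_method="complete", k=k,
        sample_ids=list(external_layer.sample_ids),
    )
    _, agreement = cluster_concordance(predicted, run.labels)
    return TransferResult(
        predictions=preds,
        predicted=predicted,
        cluster_labels=run.labels,
        agreement=agreement,
        n_features_used=len(present),
    )
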