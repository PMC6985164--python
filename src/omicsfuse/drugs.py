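"""Nearest-neighbour drug-response inference and ordinal agreement scoring.

A cell line's response to a drug is inferred from the responses of the
cell lines most similar to it in biomarker-expression space: an
exhaustive nearest-neighbour search under squared Euclidean distance
returns the ten most similar reference lines, and the median of their
z-scored activity areas for each drug is categorized on an ordinal
scale (resistant / intermediate / sensitive at z thresholds of ±0.8).
Predicted and observed categories are compared with the quadratic
weighted Cohen's kappa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DrugResponseTable",
    "NeighborSearcher",
    "KappaResult",
    "categorize_z",
    "find_neighbors",
    "predict_drug_response",
    "quadratic_kappa",
    "leave_one_out_benchmark",
    "RESISTANT",
    "INTERMEDIATE",
    "SENSITIVE",
]

RESISTANT, INTERMEDIATE, SENSITIVE = 0, 1, 2

#: z-score beyond which an activity area counts as sensitive (+) / resistant (−)
Z_THRESHOLD = 0.8


def categorize_z(z, threshold: float = Z_THRESHOLD):
    """Ordinal sensitivity category of z-scored activity areas.

    Strict inequalities: ``z > threshold`` is sensitive, ``z < -threshold``
    resistant, everything in between — including the boundaries
    themselves — intermediate.  NaN stays NaN.
    """
    z = np.asarray(z, dtype=float)
    cat = np.full(z.shape, float(INTERMEDIATE))
    cat[z > threshold] = SENSITIVE
    cat[z < -threshold] = RESISTANT
    cat[np.isnan(z)] = np.nan
    return cat


@dataclass
class DrugResponseTable:
    """Cell line x drug activity areas with per-drug z-scores and categories.

    ``activity`` may contain NaN (unmeasured pairs); ``z`` is column-wise
    z-scored over the non-missing lines of each drug; ``categories`` uses
    the ±0.8 ordinal rule.
    """

    line_ids: list[str]
    drug_ids: list[str]
    activity: np.ndarray
    z: np.ndarray
    categories: np.ndarray

    @classmethod
    def from_activity(
        cls,
        line_ids: list[str],
        drug_ids: list[str],
        activity: np.ndarray,
        threshold: float = Z_THRESHOLD,
    ) -> "DrugResponseTable":
        activity = np.asarray(activity, dtype=float)
        if activity.shape != (len(line_ids), len(drug_ids)):
            raise ValueError("activity shape does not match line/drug ids")
        z = np.full_like(activity, np.nan)
        for d in range(activity.shape[1]):
            col = activity[:, d]
            ok = ~np.isnan(col)
            if ok.sum() < 2:
                continue
            sd = np.std(col[ok], ddof=1)
            if sd <= 0:
                raise ValueError(
                    f"drug {drug_ids[d]!r}: zero variance across lines, z-score undefined"
                )
            z[ok, d] = (col[ok] - np.mean(col[ok])) / sd
        return cls(
            line_ids=list(line_ids),
            drug_ids=list(drug_ids),
            activity=activity,
            z=z,
            categories=categorize_z(z, threshold),
        )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def line_index(self, line_id: str) -> int:
        return self.line_ids.index(line_id)

    def has_data(self, line_id: str) -> bool:
        return bool(np.any(~np.isnan(self.activity[self.line_index(line_id)])))

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.activity, index=self.line_ids, columns=self.drug_ids)
        df.index.name = "line_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, threshold: float = Z_THRESHOLD) -> "DrugResponseTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_activity(
            line_ids=[str(i) for i in df.index],
            drug_ids=[str(c) for c in df.columns],
            activity=df.to_numpy(dtype=float),
            threshold=threshold,
        )


@dataclass
class NeighborSearcher:
    """Exhaustive nearest-neighbour searcher over biomarker profiles.

    Reference profiles are standard-normalized per feature (unless
    ``standardize=False``); queries are compared under squared Euclidean
    distance against every stored profile.
    """

    ids: list[str]
    profiles: np.ndarray
    feature_ids: list[str]
    _mean: np.ndarray = field(init=False, repr=False)
    _sd: np.ndarray = field(init=False, repr=False)

    def __init__(
        self,
        ids: list[str],
        profiles: np.ndarray,
        feature_ids: list[str],
        standardize: bool = True,
    ) -> None:
        profiles = np.asarray(profiles, dtype=float)
        if profiles.shape != (len(ids), len(feature_ids)):
            raise ValueError("profile matrix shape does not match ids/features")
        if standardize:
            self._mean = profiles.mean(axis=0)
            sd = profiles.std(axis=0, ddof=1) if len(ids) > 1 else np.ones(profiles.shape[1])
            sd = np.where(sd > 0, sd, 1.0)
            self._sd = sd
            profiles = (profiles - self._mean) / self._sd
        else:
            self._mean = np.zeros(profiles.shape[1])
            self._sd = np.ones(profiles.shape[1])
        self.ids = list(ids)
        self.profiles = profiles
        self.feature_ids = list(feature_ids)

    def transform(self, raw: np.ndarray) -> np.ndarray:
        return (np.asarray(raw, dtype=float) - self._mean) / self._sd


def find_neighbors(
    searcher: NeighborSearcher,
    query_id: str | None = None,
    query_profile: np.ndarray | None = None,
    n: int = 10,
    feature_ids: list[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """The ``n`` reference profiles closest to the query, ascending.

    Distances are squared Euclidean; the query itself (by id) is
    excluded; ties are broken by lexicographic id order.  Queries given
    as raw profiles must carry exactly the searcher's feature ids.
    """
    if query_id is not None and query_id in searcher.ids:
        q = searcher.profiles[searcher.ids.index(query_id)]
    elif query_profile is not None:
        if feature_ids is not None and list(feature_ids) != searcher.feature_ids:
            raise ValueError("query feature ids do not match searcher feature ids")
        q = searcher.transform(query_profile)
    else:
        raise ValueError(f"query {query_id!r} not found and no profile supplied")

    d2 = np.sum((searcher.profiles - q) ** 2, axis=1)
    candidates = [
        (float(d2[i]), searcher.ids[i], i)
        for i in range(len(searcher.ids))
        if searcher.ids[i] != query_id
    ]
    if n >= len(candidates):
        logger.warning(
            "requested %d neighbours but only %d references available; returning all",
            n,
            len(candidates),
        )
        n = len(candidates)
    candidates.sort(key=lambda c: (c[0], c[1]))
    if any(candidates[i][0] == candidates[i + 1][0] for i in range(n - 1)):
        logger.info("neighbour distance ties broken by id order")
    top = candidates[:n]
    return [c[1] for c in top], np.array([c[0] for c in top])


def predict_drug_response(
    query_id: str,
    searcher: NeighborSearcher,
    table: DrugResponseTable,
    n: int = 10,
    threshold: float = Z_THRESHOLD,
) -> np.ndarray:
    """Per-drug predicted ordinal category for one query line.

    The query's ``n`` nearest neighbours are looked up in the drug
    table; neighbours with no drug data are skipped (the search is not
    widened).  For each drug the prediction is the category of the
    median of the data-bearing neighbours' z-scores; drugs with no
    neighbour data come back NaN.
    """
    neighbor_ids, _ = find_neighbors(searcher, query_id=query_id, n=n)
    in_table = [i for i in neighbor_ids if i in table.line_ids and table.has_data(i)]
    if not in_table:
        raise ValueError(f"no neighbour of {query_id!r} has drug-response data")
    rows = np.array([table.z[table.line_index(i)] for i in in_table])
    pred = np.full(table.n_drugs, np.nan)
    for d in range(table.n_drugs):
        vals = rows[:, d]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            pred[d] = categorize_z(np.median(vals), threshold)
    return pred


def quadratic_kappa(pred, actual, n_categories: int = 3) -> float:
    """Quadratic weighted Cohen's kappa between two ordinal vectors.

    kappa = 1 − Σ w·O / Σ w·E with weights w_ij = (i−j)²/(C−1)², O the
    observed contingency table and E the outer product of the marginals
    scaled to the total count; the full C x C grid is used even when
    categories are unobserved.  Pairs with a missing entry are dropped.
    Two constant, identical vectors score 1 by convention.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if pred.shape != actual.shape:
        raise ValueError("pred and actual must have equal length")
    ok = ~(np.isnan(pred) | np.isnan(actual))
    pred, actual = pred[ok], actual[ok]
    if pred.size == 0:
        raise ValueError("no usable (non-missing) prediction/observation pairs")
    C = n_categories
    if np.any((pred < 0) | (pred > C - 1)) or np.any((actual < 0) | (actual > C - 1)):
        raise ValueError(f"categories must lie in 0..{C - 1}")

    O = np.zeros((C, C))
    for p_, a_ in zip(pred.astype(int), actual.astype(int)):
        O[p_, a_] += 1
    total = O.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / total
    idx = np.arange(C)
    w = (idx[:, None] - idx[None, :]) ** 2 / (C - 1) ** 2 if C > 1 else np.zeros((1, 1))
    denom = float((w * E).sum())
    if denom == 0.0:
        # both raters constant and identical
        return 1.0
    return 1.0 - float((w * O).sum()) / denom


@dataclass
class KappaResult:
    """Leave-one-out benchmark summary: per-line and mean kappa."""

    per_line: dict[str, float]
    mean_kappa: float
    n_drugs: int
    pooled: bool = False


def leave_one_out_benchmark(
    table: DrugResponseTable,
    searcher: NeighborSearcher,
    n: int = 10,
    threshold: float = Z_THRESHOLD,
) -> KappaResult:
    """Predict every data-bearing line from its neighbours and score kappa.

    Each line with observed drug data is predicted from its nearest
    neighbours (itself excluded) and the quadratic kappa between its
    predicted and observed categories is recorded; the mean over lines
    is the headline statistic.  With a single-drug table, per-line kappa
    is degenerate, so one kappa is computed pooled across lines instead.
    """
    lines = [i for i in table.line_ids if i in searcher.ids and table.has_data(i)]
    if len(lines) < 2:
        raise ValueError("need at least two lines with drug data")

    preds: dict[str, np.ndarray] = {}
    for line in lines:
        try:
            preds[line] = predict_drug_response(line, searcher, table, n=n, threshold=threshold)
        except ValueError as exc:  # no data-bearing neighbour
            logger.warning("skipping %s: %s", line, exc)

    if table.n_drugs == 1:
        logger.info("single-drug table: computing kappa pooled across lines")
        pooled_pred = np.array([preds[i][0] for i in preds])
        pooled_act = np.array([table.categories[table.line_index(i), 0] for i in preds])
        k = quadratic_kappa(pooled_pred, pooled_act)
        return KappaResult(per_line={}, mean_kappa=k, n_drugs=1, pooled=True)

    per_line: dict[str, float] = {}
    for line, pred in preds.items():
        actual = table.categories[table.line_index(line)]
        try:
            per_line[line] = quadratic_kappa(pred, actual)
        except ValueError as exc:
            logger.warning("no usable drug pairs for %s: %s", line, exc)
    if not per_line:
        raise ValueError("no line could be scored")
    return KappaResult(
        per_line=per_line,
        mean_kappa=float(np.mean(list(per_line.values()))),
        n_drugs=table.n_drugs,
    )
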