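"""Differential testing, enrichment and survival analysis between subtypes.

Welch's unequal-variance t-test per feature with Benjamini-Hochberg FDR
control, upper-tail hypergeometric gene-set enrichment (GMT input),
Kaplan-Meier curves with log-rank comparison, and categorical
association tests (Pearson chi-square; Fisher's exact for 2x2 tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import SurvivalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DiffResult",
    "EnrichmentResult",
    "KMResult",
    "welch_bh",
    "hypergeom_enrich",
    "read_gmt",
    "km_curves",
    "categorical_assoc",
]


@dataclass
class DiffResult:
    feature_id: str
    mean_1: float
    mean_2: float
    t_statistic: float
    p: float
    q: float
    direction: str  # "up-in-1" | "up-in-2"
    degenerate: bool = False


def welch_bh(
    X: np.ndarray, labels: np.ndarray, fdr: float = 0.05, feature_ids=None
) -> list[DiffResult]:
    """Welch t-test per feature between two groups, BH-adjusted.

    Features with zero variance in both groups (no test possible) get
    p = 1 and a ``degenerate`` flag.  Significance is q < ``fdr``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"exactly two groups required, got {groups.size}")
    A = X[labels == groups[0]]
    B = X[labels == groups[1]]
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("both groups need at least two samples")

    p_feats = X.shape[1]
    fids = list(feature_ids) if feature_ids is not None else [f"f{j:04d}" for j in range(p_feats)]
    tvals = np.zeros(p_feats)
    pvals = np.ones(p_feats)
    degen = np.zeros(p_feats, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(A, B, axis=0, equal_var=False, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    degen[bad] = True
    tvals[~bad] = t[~bad]
    pvals[~bad] = p[~bad]
    if bad.any():
        logger.warning("%d features with undefined Welch t (zero variance): p set to 1", bad.sum())

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for j in range(p_feats):
        m1, m2 = float(np.nanmean(A[:, j])), float(np.nanmean(B[:, j]))
        out.append(
            DiffResult(
                feature_id=fids[j],
                mean_1=m1,
                mean_2=m2,
                t_statistic=float(tvals[j]),
                p=float(pvals[j]),
                q=float(qvals[j]),
                direction="up-in-1" if m1 >= m2 else "up-in-2",
                degenerate=bool(degen[j]),
            )
        )
    return out


@dataclass
class EnrichmentResult:
    term_id: str
    set_size: int
    overlap: int
    p: float
    q: float


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def hypergeom_enrich(
    query_list, gene_sets: dict[str, set[str]], universe
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of each gene set.

    p = P(overlap >= observed) drawing |query| genes without replacement
    from a universe containing the (universe-intersected) set; BH across
    terms.
    """
    universe = set(universe)
    query = set(query_list)
    if not universe or not query:
        raise ValueError("query list and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query list must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = []
    for term, genes in gene_sets.items():
        genes = genes & universe
        n = len(genes)
        k = len(genes & query)
        p = float(sps.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append((term, n, k, min(p, 1.0)))
    _, qvals, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    return [
        EnrichmentResult(term_id=t, set_size=n, overlap=k, p=p, q=float(q))
        for (t, n, k, p), q in zip(rows, qvals)
    ]


@dataclass
class KMResult:
    survival_functions: dict[int, pd.DataFrame]
    medians: dict[int, float]  # NaN = not reached
    logrank_p: float | None
    logrank_statistic: float | None


def km_curves(records: list[SurvivalRecord]) -> KMResult:
    """Kaplan-Meier product-limit curves per group with a log-rank test.

    Median survival is the smallest time with S(t) <= 0.5 (NaN when not
    reached).  Two groups get the standard two-sample log-rank test;
    more groups get the multivariate version.
    """
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    groups = np.array([r.group for r in records])
    uniq = np.unique(groups)

    sfs: dict[int, pd.DataFrame] = {}
    medians: dict[int, float] = {}
    for g in uniq:
        m = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m], label=str(g))
        sfs[int(g)] = kmf.survival_function_
        med = kmf.median_survival_time_
        medians[int(g)] = float(med) if np.isfinite(med) else float("nan")
        if not events[m].any():
            logger.warning("group %s has no events: median not reached", g)

    lr_p = lr_stat = None
    if uniq.size == 2 and events.any():
        m0 = groups == uniq[0]
        res = logrank_test(times[m0], times[~m0], events[m0], events[~m0])
        lr_p, lr_stat = float(res.p_value), float(res.test_statistic)
    elif uniq.size > 2 and events.any():
        res = multivariate_logrank_test(times, groups, events)
        lr_p, lr_stat = float(res.p_value), float(res.test_statistic)
    return KMResult(
        survival_functions=sfs, medians=medians, logrank_p=lr_p, logrank_statistic=lr_stat
    )


def categorical_assoc(table: np.ndarray) -> tuple[float, float, float | None]:
    """Association in an r x c contingency table.

    Returns (chi-square statistic, chi-square p, Fisher exact p) — the
    Fisher p only for 2x2 tables.  Pearson chi-square is computed
    without continuity correction; zero-margin rows/columns are dropped
    with a warning.
    """
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("contingency table must hold nonnegative integers")
        table = table.astype(int)
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not (keep_r.all() and keep_c.all()):
        logger.warning("dropping zero-margin rows/columns from contingency table")
        table = table[keep_r][:, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs at least 2x2 non-empty margins")
    chi2, chi_p, _, _ = sps.chi2_contingency(table, correction=False)
    fisher_p = None
    if table.shape == (2, 2):
        _, fisher_p = sps.fisher_exact(table, alternative="two-sided")
        fisher_p = float(fisher_p)
    return float(chi2), float(chi_p), fisher_p
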