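"""Shared in-memory containers for the subtyping pipeline.

All containers are thin dataclasses around numpy arrays plus ordered
identifier lists, with TSV round-trip helpers (samples in rows, a header
row of feature ids, first column of sample ids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsLayer",
    "AffinityNetwork",
    "SubtypeAssignment",
    "BiomarkerPanel",
    "SurvivalRecord",
]


@dataclass
class OmicsLayer:
    """One molecular data type as a sample x feature numeric matrix.

    Parameters
    ----------
    name
        Layer label, conventionally one of ``{"mRNA", "protein", "miRNA",
        "methylation"}`` but any string is accepted.
    sample_ids, feature_ids
        Ordered, unique identifiers for rows and columns of ``values``.
    values
        ``(n_samples, n_features)`` float array.  Missing values (NaN)
        are permitted until preprocessing imputes them.
    """

    name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} does not "
                f"match {len(self.sample_ids)} sample ids x {len(self.feature_ids)} feature ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"layer {self.name!r}: duplicate sample ids")
        if len(set(self.feature_ids)) != p:
            raise ValueError(f"layer {self.name!r}: duplicate feature ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "other") -> "OmicsLayer":
        return cls(
            name=name,
            sample_ids=[str(s) for s in df.index],
            feature_ids=[str(f) for f in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, name: str = "other") -> "OmicsLayer":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df, name=name)


@dataclass
class AffinityNetwork:
    """Symmetric nonnegative sample x sample similarity matrix."""

    sample_ids: list[str]
    W: np.ndarray

    _SYM_TOL = 1e-10

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.sample_ids)
        if self.W.shape != (n, n):
            raise ValueError(f"W shape {self.W.shape} does not match {n} sample ids")
        if np.any(self.W < 0):
            raise ValueError("affinity matrix has negative entries")
        if not np.allclose(self.W, self.W.T, atol=self._SYM_TOL, rtol=0.0):
            raise ValueError("affinity matrix is not symmetric to tolerance 1e-10")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "AffinityNetwork":
        df = pd.read_csv(path, sep="\t", index_col=0)
        W = df.to_numpy(dtype=float)
        return cls(sample_ids=[str(s) for s in df.index], W=(W + W.T) / 2.0)


@dataclass
class SubtypeAssignment:
    """Per-sample cluster or class labels, with optional posteriors.

    Labels are small integers (1-based for generated data, but any
    integer coding is accepted); ``posterior`` when present is an
    ``(n_samples, n_classes)`` row-stochastic matrix.
    """

    sample_ids: list[str]
    labels: np.ndarray
    posterior: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.sample_ids) != self.labels.shape[0]:
            raise ValueError("label vector length does not match sample ids")
        if self.posterior is not None:
            self.posterior = np.asarray(self.posterior, dtype=float)
            if self.posterior.shape[0] != len(self.sample_ids):
                raise ValueError("posterior rows do not match sample ids")
            if not np.allclose(self.posterior.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("posterior rows must sum to 1")

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)

    def write_tsv(self, path) -> None:
        pd.DataFrame({"sample_id": self.sample_ids, "subtype": self.labels}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path) -> "SubtypeAssignment":
        df = pd.read_csv(path, sep="\t")
        return cls(
            sample_ids=[str(s) for s in df.iloc[:, 0]],
            labels=df.iloc[:, 1].to_numpy(),
        )


@dataclass
class BiomarkerPanel:
    """Learned per-feature weights and the selected subset for one layer."""

    layer_name: str
    feature_ids: list[str]
    weights: np.ndarray
    selected: list[str] = field(default_factory=list)
    lam: float = 0.0
    objective_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != len(self.feature_ids):
            raise ValueError("weights length does not match feature ids")
        if np.any(self.weights < 0):
            raise ValueError("panel weights must be nonnegative")
        if self.lam < 0:
            raise ValueError("regularization strength must be >= 0")
        unknown = set(self.selected) - set(self.feature_ids)
        if unknown:
            raise ValueError(f"selected features not in panel: {sorted(unknown)[:5]}")

    def weight_of(self, feature_id: str) -> float:
        return float(self.weights[self.feature_ids.index(feature_id)])

    def write_tsv(self, path) -> None:
        sel = set(self.selected)
        pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "weight": self.weights,
                "selected": [int(f in sel) for f in self.feature_ids],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class SurvivalRecord:
    """One sample's follow-up: time on study, event flag, group label."""

    sample_id: str
    time: float
    event: bool
    group: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"survival time must be positive, got {self.time}")
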