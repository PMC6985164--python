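"""Synthetic multi-omics cohorts with planted subtype structure.

The generator emulates the design of a small integrative tumour-profiling
study: a few dozen samples measured on four molecular layers (mRNA,
protein, miRNA, DNA methylation), each layer carrying a handful of
informative features among many nuisance features.  Per-layer signal can
be made deliberately *discordant* — a fraction of samples have their
informative signature swapped with samples of the other subtype in that
layer only — so that single-layer clusterings disagree with the truth
while a fused multi-layer clustering can still recover it.  Companion
generators produce cell-line drug-response panels whose activity areas
depend stochastically on subtype, and subtype-dependent exponential
survival times with independent censoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import OmicsLayer, SubtypeAssignment, SurvivalRecord
from .drugs import DrugResponseTable

logger = logging.getLogger(__name__)

__all__ = [
    "LayerSpec",
    "SynthConfig",
    "SyntheticDataset",
    "standard_scenario",
    "generate_multiomics",
    "generate_drug_panel",
    "generate_survival",
]


@dataclass(frozen=True)
class LayerSpec:
    """Recipe for one molecular layer.

    ``effect_size`` is the standardized between-subtype mean shift of an
    informative feature (shift / noise_sd); ``discordance_fraction`` is
    the fraction of samples whose informative signature is permuted
    across subtypes in this layer only.
    """

    name: str
    n_features: int
    n_informative: int
    effect_size: float = 2.0
    noise_sd: float = 1.0
    discordance_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_informative < 0:
            raise ValueError(f"layer {self.name!r}: non-positive dimensions")
        if self.n_informative > self.n_features:
            raise ValueError(
                f"layer {self.name!r}: n_informative ({self.n_informative}) "
                f"> n_features ({self.n_features})"
            )
        if not 0.0 <= self.discordance_fraction < 1.0:
            raise ValueError(f"layer {self.name!r}: discordance_fraction must be in [0,1)")
        if self.effect_size < 0:
            raise ValueError(f"layer {self.name!r}: effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError(f"layer {self.name!r}: noise_sd must be > 0")


@dataclass(frozen=True)
class SynthConfig:
    """Full recipe for a synthetic cohort (layers + survival)."""

    n_samples: int
    layer_specs: tuple[LayerSpec, ...]
    n_subtypes: int = 2
    seed: int = 0
    censor_rate: float = 0.0
    survival_scale_per_subtype: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.n_subtypes < 1:
            raise ValueError("n_subtypes must be positive")
        if self.n_subtypes > self.n_samples:
            raise ValueError(
                f"n_subtypes ({self.n_subtypes}) exceeds n_samples ({self.n_samples})"
            )
        if not self.layer_specs:
            raise ValueError("at least one layer spec required")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0,1]")
        if any(s <= 0 for s in self.survival_scale_per_subtype):
            raise ValueError("survival scales must be positive")


@dataclass
class SyntheticDataset:
    """Generated cohort: layers, ground-truth labels, informative ids."""

    layers: list[OmicsLayer]
    true_labels: SubtypeAssignment
    informative_features: dict[str, set[str]] = field(default_factory=dict)

    def layer(self, name: str) -> OmicsLayer:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise KeyError(name)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lay in self.layers:
            lay.write_tsv(outdir / f"layer_{lay.name}.tsv")
        self.true_labels.write_tsv(outdir / "truth.tsv")


def standard_scenario(seed: int = 0, n_samples: int = 45, n_subtypes: int = 2) -> SynthConfig:
    """The package's reference cohort design.

    45 samples, two subtypes and four layers; three of the four layers
    carry 40% discordant samples (minimally overlapping sets), so each
    single-layer clustering is unreliable while the consensus is intact.
    Effect size 2, unit noise throughout; feature counts reflect the
    relative dimensionality of the four platforms at desk scale.
    """
    return SynthConfig(
        n_samples=n_samples,
        n_subtypes=n_subtypes,
        seed=seed,
        layer_specs=(
            LayerSpec("mRNA", 200, 40, 2.0, 1.0, 0.4),
            LayerSpec("protein", 100, 20, 2.0, 1.0, 0.4),
            LayerSpec("miRNA", 60, 12, 2.0, 1.0, 0.4),
            LayerSpec("methylation", 200, 40, 2.0, 1.0, 0.0),
        ),
        censor_rate=0.2,
        survival_scale_per_subtype=(25.0, 15.0),
    )


def _subtype_labels(n_samples: int, n_subtypes: int) -> np.ndarray:
    # near-balanced, deterministic: sample i -> 1 + (i * k) // n
    return 1 + (np.arange(n_samples) * n_subtypes) // n_samples


def _informative_means(
    labels: np.ndarray, spec: LayerSpec, n_subtypes: int
) -> np.ndarray:
    """Mean matrix (n_samples x n_informative) for the informative block.

    Informative feature j is elevated (by effect_size * noise_sd) in
    subtype ``1 + j % n_subtypes``.  The pattern depends only on the
    feature index, never the seed, so feature semantics are consistent
    across independently generated cohorts.
    """
    n = labels.shape[0]
    shift = spec.effect_size * spec.noise_sd
    means = np.zeros((n, spec.n_informative))
    for j in range(spec.n_informative):
        target = 1 + j % n_subtypes
        means[labels == target, j] = shift
    return means


def _discordant_window(order: np.ndarray, start: int, size: int) -> np.ndarray:
    """Contiguous window (wrapping) in a fixed shuffled sample order.

    Consecutive layers take consecutive windows, so discordant sets
    across layers overlap as little as the fractions allow.
    """
    n = order.shape[0]
    idx = [(start + i) % n for i in range(size)]
    return order[idx]


def _permute_across_subtypes(
    block: np.ndarray,
    members: np.ndarray,
    labels: np.ndarray,
    crossed: set[int],
    rng: np.random.Generator,
) -> None:
    """Permute informative sub-rows among the discordant ``members``.

    Roughly half the members swap signatures pairwise with a member of
    another subtype (these are the samples the layer now misleads); the
    rest rotate within their own subtype (shuffled but still coherent).
    Feature-wise marginals are preserved either way.  Samples already
    subtype-crossed in a previous layer (``crossed``) only rotate
    within-subtype here, so no sample carries a wrong-subtype signature
    in more than one layer and the cross-layer consensus stays
    recoverable.
    """
    if members.size < 2:
        return
    member_subtypes = np.unique(labels[members])
    eligible = [int(i) for i in members if int(i) not in crossed]
    pools = {
        s: [i for i in eligible if labels[i] == s] for s in member_subtypes
    }
    for s in pools:
        pools[s] = list(rng.permutation(pools[s])) if pools[s] else []
    # pair across subtypes until ~half the window has crossed
    target = members.size // 2
    pairs: list[tuple[int, int]] = []
    if member_subtypes.size >= 2:
        while 2 * len(pairs) + 2 <= target + 1:
            sizes = sorted(pools, key=lambda s: -len(pools[s]))
            a, b = sizes[0], sizes[1]
            if not pools[a] or not pools[b]:
                break
            pairs.append((pools[a].pop(), pools[b].pop()))
    for i, j in pairs:
        block[[i, j], :] = block[[j, i], :]
        crossed.update((i, j))
    # remaining members rotate within their own subtype
    swapped = {i for pair in pairs for i in pair}
    for s in member_subtypes:
        rest = [int(i) for i in members if labels[i] == s and int(i) not in swapped]
        if len(rest) >= 2:
            block[rest, :] = block[np.roll(rest, 1), :]


def generate_multiomics(config: SynthConfig) -> SyntheticDataset:
    """Generate a multi-layer cohort with planted subtypes.

    Informative features carry a standardized between-subtype mean shift
    of ``effect_size``; nuisance features are exchangeable Gaussian
    noise.  In each layer a ``discordance_fraction`` of samples have
    their informative-feature rows permuted across subtypes.  Bitwise
    reproducible for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    labels = _subtype_labels(n, config.n_subtypes)
    sample_ids = [f"S{i:03d}" for i in range(n)]

    # one shuffled order shared by all layers; rolling windows keep the
    # discordant sets as close to disjoint as the fractions allow
    shuffled = rng.permutation(n)
    window_start = 0
    crossed: set[int] = set()

    layers: list[OmicsLayer] = []
    informative: dict[str, set[str]] = {}
    for spec in config.layer_specs:
        p, k = spec.n_features, spec.n_informative
        X = rng.normal(0.0, spec.noise_sd, size=(n, p))
        X[:, :k] += _informative_means(labels, spec, config.n_subtypes)

        m = int(round(spec.discordance_fraction * n))
        if m >= 2 and k > 0:
            members = _discordant_window(shuffled, window_start, m)
            window_start += m
            _permute_across_subtypes(X[:, :k], members, labels, crossed, rng)

        feature_ids = [f"{spec.name}_f{j:04d}" for j in range(p)]
        informative[spec.name] = set(feature_ids[:k])
        perm = rng.permutation(p)
        layers.append(
            OmicsLayer(
                name=spec.name,
                sample_ids=sample_ids,
                feature_ids=[feature_ids[j] for j in perm],
                values=X[:, perm],
            )
        )

    truth = SubtypeAssignment(sample_ids=sample_ids, labels=labels)
    return SyntheticDataset(layers=layers, true_labels=truth, informative_features=informative)


def generate_drug_panel(
    labels: SubtypeAssignment,
    n_drugs: int = 24,
    subtype_effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> DrugResponseTable:
    """Cell-line drug activity areas that depend stochastically on subtype.

    Each drug's activity area is a subtype-specific mean plus Gaussian
    noise.  Subtype means per drug are evenly spaced over
    ``[-subtype_effect, +subtype_effect]`` with an orientation that
    alternates deterministically with the drug index (so drug semantics
    are stable across seeds).  ``noise_sd = 0`` makes same-subtype lines
    identical.
    """
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    if len(labels.sample_ids) == 0:
        raise ValueError("labels must be non-empty")
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels.labels, dtype=int)
    subtypes = np.unique(lab)
    k = subtypes.size
    spacing = np.linspace(-subtype_effect, subtype_effect, k) if k > 1 else np.zeros(1)
    sub_index = np.searchsorted(subtypes, lab)

    n = lab.shape[0]
    activity = np.empty((n, n_drugs))
    for d in range(n_drugs):
        orient = 1.0 if d % 2 == 0 else -1.0
        means = orient * spacing[sub_index]
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
        activity[:, d] = means + noise

    drug_ids = [f"drug_{d:02d}" for d in range(n_drugs)]
    return DrugResponseTable.from_activity(
        line_ids=list(labels.sample_ids), drug_ids=drug_ids, activity=activity
    )


def generate_survival(labels: SubtypeAssignment, config: SynthConfig) -> list[SurvivalRecord]:
    """Subtype-dependent exponential survival with independent censoring.

    Event times are exponential with the subtype's scale (mean) from
    ``config.survival_scale_per_subtype``; with probability
    ``censor_rate`` a record is censored at a uniform fraction of its
    event time.
    """
    lab = np.asarray(labels.labels, dtype=int)
    subtypes = np.unique(lab)
    scales = config.survival_scale_per_subtype
    if len(scales) != subtypes.size:
        raise ValueError(
            f"survival_scale_per_subtype has {len(scales)} entries "
            f"for {subtypes.size} subtypes"
        )
    rng = np.random.default_rng(config.seed + 1)
    records: list[SurvivalRecord] = []
    for sid, s in zip(labels.sample_ids, lab):
        scale = scales[int(np.searchsorted(subtypes, s))]
        t = float(rng.exponential(scale))
        censored = bool(rng.random() < config.censor_rate)
        if censored:
            t *= float(rng.uniform(1e-9, 1.0))
        records.append(
            SurvivalRecord(sample_id=sid, time=max(t, 1e-9), event=not censored, group=int(s))
        )
    return records
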