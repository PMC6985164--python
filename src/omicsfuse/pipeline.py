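"""End-to-end orchestration: simulate → fuse → cluster → biomarkers →
classify → transfer → drug-predict → stats.

Each stage writes its outputs plus a sidecar JSON carrying provenance
(config hash, seed, stage version); a rerun on an unchanged workspace
skips every stage whose outputs and checksums are intact.  The final
report aggregates the headline numbers of every stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import cohort_transfer, cubic_knn_spec, train
from .clustering import cluster_concordance, kmeans_select_k
from .containers import OmicsLayer, SubtypeAssignment
from .drugs import NeighborSearcher, leave_one_out_benchmark
from .nca import fit_nca_weights, select_panel
from .snf import SNFParams, snf_cluster, standardize_layer
from .stats import km_curves, welch_bh
from .synthetic import (
    SynthConfig,
    generate_drug_panel,
    generate_multiomics,
    generate_survival,
    standard_scenario,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

STAGES = [
    "simulate",
    "fuse",
    "cluster",
    "biomarkers",
    "classify",
    "transfer",
    "drugs",
    "stats",
]


@dataclass
class PipelineConfig:
    """Everything one full run needs, in one auditable object."""

    outdir: Path
    seed: int = 0
    synth: SynthConfig | None = None
    layer_paths: dict[str, Path] = field(default_factory=dict)
    snf_params: SNFParams = field(default_factory=SNFParams)
    n_clusters: int | None = 2  # None = eigengap
    panel_layer: str = "methylation"
    panel_size: int = 50
    classifier_family: str = "knn"
    n_drugs: int = 24
    drug_subtype_effect: float = 2.0
    drug_noise_sd: float = 1.0
    n_neighbors_drugs: int = 10

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.synth is None and not self.layer_paths:
            self.synth = standard_scenario(seed=self.seed)

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "synth": asdict(self.synth) if self.synth else None,
            "layers": {k: str(v) for k, v in self.layer_paths.items()},
            "snf": asdict(self.snf_params),
            "n_clusters": self.n_clusters,
            "panel_layer": self.panel_layer,
            "panel_size": self.panel_size,
            "classifier": self.classifier_family,
            "drugs": [self.n_drugs, self.drug_subtype_effect, self.drug_noise_sd,
                      self.n_neighbors_drugs],
            "version": __version__,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def validate_inputs(paths: dict[str, Path]) -> tuple[dict[str, OmicsLayer], list[str]]:
    """Parse and cross-check layer TSVs before any computation.

    Returns (layers, findings); findings list every violation with its
    file and coordinates.  An empty findings list means a clean workspace.
    """
    findings: list[str] = []
    layers: dict[str, OmicsLayer] = {}
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            findings.append(f"{path}: file not found")
            continue
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            findings.append(f"{path}: unparseable ({exc})")
            continue
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            findings.append(f"{path}: duplicate sample id {dup!r}")
            continue
        bad = df.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            findings.append(
                f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
            continue
        layers[name] = OmicsLayer.from_frame(df.astype(float), name=name)
    if len(layers) > 1:
        ref_name = next(iter(layers))
        ref = set(layers[ref_name].sample_ids)
        for name, lay in layers.items():
            diff = ref ^ set(lay.sample_ids)
            if diff:
                findings.append(
                    f"sample sets differ between {ref_name!r} and {name!r}: "
                    f"symmetric difference {sorted(diff)[:5]}"
                )
    return layers, findings


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _StageRunner:
    """Stage bookkeeping: provenance sidecars + checksum-based resume."""

    def __init__(self, outdir: Path, config_hash: str, seed: int):
        self.outdir = outdir
        self.config_hash = config_hash
        self.seed = seed
        outdir.mkdir(parents=True, exist_ok=True)

    def sidecar(self, stage: str) -> Path:
        return self.outdir / f"{stage}.provenance.json"

    def is_done(self, stage: str) -> bool:
        sc = self.sidecar(stage)
        if not sc.exists():
            return False
        try:
            meta = json.loads(sc.read_text())
        except json.JSONDecodeError:
            return False
        if meta.get("config_hash") != self.config_hash:
            return False
        for fname, digest in meta.get("outputs", {}).items():
            f = self.outdir / fname
            if not f.exists() or _file_digest(f) != digest:
                return False
        return True

    def finish(self, stage: str, outputs: list[Path], extra: dict) -> None:
        meta = {
            "stage": stage,
            "stage_version": __version__,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "outputs": {p.name: _file_digest(p) for p in outputs},
            **extra,
        }
        self.sidecar(stage).write_text(json.dumps(meta, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the aggregated report dict.

    Stages whose outputs are present with matching checksums (and an
    unchanged config) are skipped.  A stage failure raises with the
    stage name so the run can be reproduced from the command line.
    """
    out = config.outdir
    runner = _StageRunner(out, config.digest(), config.seed)
    report: dict = {"seed": config.seed, "config_hash": config.digest(), "stages": {}}
    state: dict = {}

    for stage in STAGES:
        fn = _STAGE_FNS[stage]
        if runner.is_done(stage):
            logger.info("stage %s: outputs up to date, skipping", stage)
            block = json.loads(runner.sidecar(stage).read_text()).get("report", {})
            block["skipped"] = True
            report["stages"][stage] = block
            _reload_state(stage, out, config, state)
            continue
        try:
            block, outputs = fn(config, state)
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed ({exc}); reproduce with: "
                f"omicsfuse run --outdir {out} --seed {config.seed}"
            ) from exc
        runner.finish(stage, outputs, {"report": block})
        report["stages"][stage] = block

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _reload_state(stage: str, out: Path, config: PipelineConfig, state: dict) -> None:
    """Rebuild the in-memory state a later stage needs from stage files."""
    if stage == "simulate":
        names = [s.name for s in config.synth.layer_specs] if config.synth else list(config.layer_paths)
        state["layers"] = [
            OmicsLayer.read_tsv(out / f"layer_{n}.tsv", name=n) for n in names
        ]
        truth_path = out / "truth.tsv"
        state["truth"] = SubtypeAssignment.read_tsv(truth_path) if truth_path.exists() else None
    elif stage == "cluster":
        state["fused_labels"] = SubtypeAssignment.read_tsv(out / "assignments.tsv")
    elif stage == "biomarkers":
        df = pd.read_csv(out / "panel.tsv", sep="\t")
        state["panel_features"] = list(df[df["selected"] == 1]["feature_id"])


def _stage_simulate(config: PipelineConfig, state: dict):
    out = config.outdir
    outputs = []
    if config.synth is not None:
        ds = generate_multiomics(config.synth)
        state["layers"] = ds.layers
        state["truth"] = ds.true_labels
        state["dataset"] = ds
        for lay in ds.layers:
            p = out / f"layer_{lay.name}.tsv"
            lay.write_tsv(p)
            outputs.append(p)
        tp = out / "truth.tsv"
        ds.true_labels.write_tsv(tp)
        outputs.append(tp)
        block = {"n_samples": ds.true_labels.labels.shape[0], "n_layers": len(ds.layers)}
    else:
        layers, findings = validate_inputs(config.layer_paths)
        if findings:
            raise ValueError("input validation failed: " + "; ".join(findings))
        state["layers"] = list(layers.values())
        state["truth"] = None
        block = {"n_samples": state["layers"][0].n_samples, "n_layers": len(layers)}
    return block, outputs


def _stage_fuse(config: PipelineConfig, state: dict):
    out = config.outdir
    fused, labels, k = snf_cluster(
        state["layers"], config.snf_params, k=config.n_clusters, seed=config.seed
    )
    state["fused"] = fused
    state["fused_labels"] = labels
    p = out / "fused_network.tsv"
    fused.write_tsv(p)
    return {"k": k, "n_samples": fused.n_samples}, [p]


def _stage_cluster(config: PipelineConfig, state: dict):
    out = config.outdir
    labels = state["fused_labels"]
    p = out / "assignments.tsv"
    labels.write_tsv(p)
    block = {"n_clusters": labels.n_clusters}
    # single-platform baseline on the first layer for context
    lay = standardize_layer(state["layers"][0])
    run = kmeans_select_k(lay.values, replicates=100, seed=config.seed,
                          sample_ids=lay.sample_ids)
    block["kmeans_baseline_k"] = run.k
    block["kmeans_baseline_silhouette"] = round(run.mean_silhouette, 4)
    if state.get("truth") is not None:
        ari, agree = cluster_concordance(labels, state["truth"])
        block["ari_vs_truth"] = round(ari, 4)
        block["agreement_vs_truth"] = round(agree, 4)
    return block, [p]


def _stage_biomarkers(config: PipelineConfig, state: dict):
    out = config.outdir
    lay = next(l for l in state["layers"] if l.name == config.panel_layer)
    lay = standardize_layer(lay)
    state["panel_matrix"] = lay
    panel = fit_nca_weights(
        lay.values, state["fused_labels"].labels,
        feature_ids=lay.feature_ids, layer_name=lay.name,
    )
    panel = select_panel(panel, rule="top_n", top_n=min(config.panel_size, lay.n_features))
    state["panel"] = panel
    p = out / "panel.tsv"
    panel.write_tsv(p)
    return {"layer": lay.name, "panel_size": len(panel.selected)}, [p]


def _stage_classify(config: PipelineConfig, state: dict):
    panel = state["panel"]
    lay = state["panel_matrix"]
    cols = [lay.feature_ids.index(f) for f in panel.selected]
    model = train(
        cubic_knn_spec(),
        lay.values[:, cols],
        state["fused_labels"].labels,
        feature_ids=panel.selected,
        sample_ids=lay.sample_ids,
        seed=config.seed,
    )
    state["model"] = model
    return {"family": config.classifier_family, "cv_accuracy": round(model.cv_accuracy, 4)}, []


def _stage_transfer(config: PipelineConfig, state: dict):
    if config.synth is None:
        return {"note": "no external cohort configured"}, []
    ext_cfg = SynthConfig(
        n_samples=config.synth.n_samples,
        layer_specs=config.synth.layer_specs,
        n_subtypes=config.synth.n_subtypes,
        seed=config.synth.seed + 10_000,
        censor_rate=config.synth.censor_rate,
        survival_scale_per_subtype=config.synth.survival_scale_per_subtype,
    )
    ext = generate_multiomics(ext_cfg)
    ext_lay = standardize_layer(ext.layer(config.panel_layer))
    res = cohort_transfer(state["model"], ext_lay, state["panel"], seed=config.seed)
    block = {"agreement_with_clustering": round(res.agreement, 4),
             "n_features_used": res.n_features_used,
             "low_confidence": sum(p.low_confidence for p in res.predictions)}
    pred = SubtypeAssignment(
        sample_ids=[p.sample_id for p in res.predictions],
        labels=np.array([p.label for p in res.predictions]),
    )
    _, acc = cluster_concordance(pred, ext.true_labels)
    block["agreement_vs_truth"] = round(acc, 4)
    return block, []


def _stage_drugs(config: PipelineConfig, state: dict):
    if state.get("truth") is None:
        return {"note": "no ground-truth labels; drug stage needs a simulated panel"}, []
    out = config.outdir
    table = generate_drug_panel(
        state["truth"],
        n_drugs=config.n_drugs,
        subtype_effect=config.drug_subtype_effect,
        noise_sd=config.drug_noise_sd,
        seed=config.seed + 1,
    )
    p = out / "drug_activity.tsv"
    table.write_tsv(p)
    lay = state["panel_matrix"]
    panel = state["panel"]
    cols = [lay.feature_ids.index(f) for f in panel.selected]
    searcher = NeighborSearcher(
        ids=list(lay.sample_ids),
        profiles=lay.values[:, cols],
        feature_ids=list(panel.selected),
    )
    res = leave_one_out_benchmark(table, searcher, n=config.n_neighbors_drugs)
    bench = out / "drug_benchmark.json"
    bench.write_text(json.dumps(
        {"mean_kappa": res.mean_kappa, "per_line": res.per_line}, indent=2))
    return {"mean_kappa": round(res.mean_kappa, 4), "n_drugs": res.n_drugs}, [p, bench]


def _stage_stats(config: PipelineConfig, state: dict):
    block: dict = {}
    labels = state["fused_labels"].labels
    lay = state["panel_matrix"]
    if np.unique(labels).size == 2:
        diffs = welch_bh(lay.values, labels, feature_ids=lay.feature_ids)
        block["n_significant_q05"] = int(sum(d.q < 0.05 for d in diffs))
    if config.synth is not None and config.synth.survival_scale_per_subtype:
        truth = state.get("truth")
        if truth is not None:
            records = generate_survival(truth, config.synth)
            km = km_curves(records)
            block["median_survival"] = {str(g): round(m, 2) for g, m in km.medians.items()}
            block["logrank_p"] = round(km.logrank_p, 4) if km.logrank_p is not None else None
    return block, []


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "fuse": _stage_fuse,
    "cluster": _stage_cluster,
    "biomarkers": _stage_biomarkers,
    "classify": _stage_classify,
    "transfer": _stage_transfer,
    "drugs": _stage_drugs,
    "stats": _stage_stats,
}


def load_config(path, outdir=None, seed: int | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (see README for keys)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    synth = None
    if "synth" in raw:
        s = raw["synth"]
        from .synthetic import LayerSpec

        synth = SynthConfig(
            n_samples=s["n_samples"],
            n_subtypes=s.get("n_subtypes", 2),
            seed=seed if seed is not None else s.get("seed", 0),
            layer_specs=tuple(LayerSpec(**ls) for ls in s["layers"]),
            censor_rate=s.get("censor_rate", 0.0),
            survival_scale_per_subtype=tuple(s.get("survival_scales", ())),
        )
    snf_raw = raw.get("snf", {})
    return PipelineConfig(
        outdir=Path(outdir if outdir is not None else raw.get("outdir", "omicsfuse_run")),
        seed=seed if seed is not None else raw.get("seed", 0),
        synth=synth,
        layer_paths={k: Path(v) for k, v in raw.get("layers", {}).items()},
        snf_params=SNFParams(
            n_neighbors=snf_raw.get("n_neighbors", 24),
            alpha=snf_raw.get("alpha", 0.7),
            iterations=snf_raw.get("iterations", 25),
        ),
        n_clusters=raw.get("n_clusters", 2),
        panel_layer=raw.get("panel_layer", "methylation"),
        panel_size=raw.get("panel_size", 50),
        n_drugs=raw.get("n_drugs", 24),
        drug_subtype_effect=raw.get("drug_subtype_effect", 2.0),
        drug_noise_sd=raw.get("drug_noise_sd", 1.0),
    )
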