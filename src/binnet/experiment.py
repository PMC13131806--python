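"""End-to-end experiment orchestration: simulate -> train -> attribute ->
stability, with a content-hashed manifest so every output is re-derivable
from the recorded configuration and seeds."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import attribution as _attr
from .knowledge import (
    build_layer_masks,
    parse_gene_sets,
    parse_pathway_relations,
    parse_regulatory_edges,
)
from .model import PathwayNet
from .network import ModelConfig, SparseNet, assemble_pnet
from .stability import StabilityReport, stability_report
from .synthetic import SyntheticConfig, simulate_to_dir
from .training import TrainConfig

logger = logging.getLogger(__name__)


class KnowledgePaths(BaseModel):
    model_config = ConfigDict(extra="forbid")
    relations: str
    gene_sets: str
    regulon: Optional[str] = None
    continuous: str  # modality CSV paths
    binary: Optional[str] = None
    labels: str


class AttributionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    steps: int = 64
    method: str = "riemann_mid"
    aggregate: str = "mean_abs"


class StabilitySettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_top: int = 20
    jaccard_layer: str = "gene_input"


class ExperimentConfig(BaseModel):
    """Validated experiment description (YAML-friendly).

    Exactly one of ``knowledge`` (paths to curated files plus cohort CSVs)
    or ``synthetic`` (generator settings) must be given.
    """

    model_config = ConfigDict(extra="forbid")
    knowledge: Optional[KnowledgePaths] = None
    synthetic: Optional[dict[str, Any]] = None
    model: dict[str, Any] = {}
    training: dict[str, Any] = {}
    attribution: AttributionSettings = AttributionSettings()
    stability: StabilitySettings = StabilitySettings()
    n_runs: int = 3
    seed: int = 0

    @model_validator(mode="after")
    def _one_source(self) -> "ExperimentConfig":
        if (self.knowledge is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of 'knowledge' and 'synthetic' must be supplied"
            )
        if self.knowledge is not None:
            for name in ("relations", "gene_sets", "labels", "continuous"):
                p = getattr(self.knowledge, name)
                if p and not Path(p).exists():
                    raise ValueError(f"knowledge file does not exist: {p}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cohort(kp: KnowledgePaths) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    mods = {
        "continuous": pd.read_csv(kp.continuous, index_col="sample_id"),
    }
    if kp.binary:
        mods["binary"] = pd.read_csv(kp.binary, index_col="sample_id")
    labels = pd.read_csv(kp.labels, index_col="sample_id")["label"]
    return mods, labels


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns (and writes) the manifest.

    ``n_runs`` independently seeded trainings feed the stability analysis:
    each run performs stratified k-fold CV, scores its held-out samples,
    attributes importance on them with the fold's trained parameters, and
    aggregates one importance table per run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "setup"
    timings: dict[str, float] = {}
    try:
        if cfg.synthetic is not None:
            stage = "simulate"
            syn = SyntheticConfig(**{**cfg.synthetic, "seed": cfg.seed})
            kdir = out / "knowledge"
            paths = simulate_to_dir(syn, kdir)
            kp = KnowledgePaths(
                relations=str(paths["relations"]),
                gene_sets=str(paths["gmt"]),
                regulon=str(paths["regulon"]),
                continuous=str(kdir / "continuous.csv"),
                binary=str(kdir / "binary.csv") if (kdir / "binary.csv").exists() else None,
                labels=str(kdir / "labels.csv"),
            )
        else:
            kp = cfg.knowledge
        timings["simulate"] = time.time() - t0

        stage = "parse"
        hierarchy = parse_pathway_relations(kp.relations)
        membership = parse_gene_sets(kp.gene_sets)
        regulon = parse_regulatory_edges(kp.regulon) if kp.regulon else None
        mods, labels = _load_cohort(kp)

        stage = "build-masks"
        model_cfg = ModelConfig(**{**cfg.model, "seed": cfg.seed})
        masks = build_layer_masks(
            hierarchy,
            membership,
            regulon=regulon if model_cfg.use_regulatory else None,
            n_layers=model_cfg.n_layers,
        )

        stage = "train"
        model = PathwayNet(mods, labels, masks, model_cfg)
        metrics_rows = []
        run_tables: list[pd.DataFrame] = []
        for run in range(cfg.n_runs):
            run_seed = cfg.seed + 101 * run
            t_run = time.time()
            tc = TrainConfig(**{**cfg.training, "seed": run_seed})
            folds = model.cross_validate(tc)
            per_layer: dict[str, list[pd.DataFrame]] = {
                name: [] for name in model.net.node_index
            }
            for fr in folds:
                metrics_rows.append(
                    {"run_id": run, "fold_id": fr.fold_id, "auc": fr.auc}
                )
                net = assemble_pnet(masks, model_cfg, modalities=model.modalities)
                net.set_state(fr.state)
                x_test = model.exog[fr.test_index]
                for layer in net.node_index:
                    cond = _attr.layer_conductance(
                        net, x_test, layer_name=layer,
                        steps=cfg.attribution.steps, method=cfg.attribution.method,
                    )
                    per_layer[layer].append(
                        pd.DataFrame(cond, columns=list(net.node_index[layer]))
                    )
            frames = []
            for layer, tables in per_layer.items():
                agg = _attr.aggregate_importance(
                    tables, method=cfg.attribution.aggregate
                )
                agg["layer"] = layer
                frames.append(agg)
            table = pd.concat(frames, ignore_index=True)
            table.insert(0, "run_id", run)
            table = table[["run_id", "node_id", "layer", "score"]]
            table.to_csv(out / f"importance_run{run}.csv", index=False)
            run_tables.append(table)
            timings[f"run_{run}"] = time.time() - t_run
            logger.info("run %d done in %.1fs", run, timings[f"run_{run}"])
        pd.DataFrame(metrics_rows).to_csv(out / "fold_metrics.csv", index=False)

        stage = "stability"
        report = stability_report(
            run_tables,
            n_top=cfg.stability.n_top,
            jaccard_layer=cfg.stability.jaccard_layer,
        )
        report.to_csv(out / "stability_report.csv")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed with seed {cfg.seed}: {exc}"
        ) from exc

    stage = "manifest"
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": json.loads(cfg.model_dump_json()),
        "seed": cfg.seed,
        "run_seeds": [cfg.seed + 101 * r for r in range(cfg.n_runs)],
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
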