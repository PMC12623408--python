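"""Config-driven end-to-end workflow: simulate/load -> filter -> rank ->
rules -> prune -> train -> evaluate -> score queries, with a reproducibility
manifest.

One pipeline-level seed is expanded into independent per-stage streams via
``numpy.random.SeedSequence`` spawning, so adding a stage never perturbs the
randomness of earlier ones, and re-running an identical config + seed
reproduces every artifact checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expr_io import (
    filter_genes_by_prevalence,
    read_annotation,
    read_expression,
    write_annotation,
)
from .evaluation import SplitSpec, confusion_report, score_table, stratified_split
from .pair_rules import (
    evaluate_rules,
    generate_rules,
    rank_genes,
    rank_rules,
    select_rules,
    select_top_genes,
)
from .rule_forest import (
    boruta_prune,
    predict_scores,
    train_forest,
)
from .simulate import (
    MixtureSpec,
    SimulationConfig,
    make_read_origin_refs,
    simulate_bulk,
    simulate_mixture,
    simulate_reads,
    write_fasta,
    write_fastq,
)

__all__ = ["PipelineConfig", "run_pipeline", "make_demo", "load_config"]


_SECTION_KEYS: dict[str, set[str]] = {
    "": {
        "seed",
        "simulation",
        "expression",
        "annotation",
        "query",
        "prevalence_threshold",
        "split",
        "genes",
        "rules",
        "boruta",
        "forest",
        "prediction",
    },
    "split": {"train_fraction"},
    "genes": {"n_altogether", "n_per_class", "n_trees"},
    "rules": {
        "n_altogether",
        "n_per_class",
        "gene_repetition_cap",
        "n_trees",
        "class_weights",
    },
    "boruta": {"enabled", "max_iterations", "alpha", "n_trees"},
    "forest": {"n_trees", "class_weights"},
    "prediction": {"missing_policy", "max_missing_fraction"},
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline parameters (unknown keys are rejected)."""

    seed: int = 0
    simulation: dict | None = None
    expression: str | None = None
    annotation: str | None = None
    query: str | None = None
    prevalence_threshold: float = 0.8
    split: dict = dataclasses.field(default_factory=lambda: {"train_fraction": 0.6})
    genes: dict = dataclasses.field(
        default_factory=lambda: {"n_altogether": 30, "n_per_class": 30, "n_trees": 2000}
    )
    rules: dict = dataclasses.field(
        default_factory=lambda: {
            "n_altogether": 100,
            "n_per_class": 100,
            "gene_repetition_cap": 1,
            "n_trees": 500,
            "class_weights": "inverse_frequency",
        }
    )
    boruta: dict = dataclasses.field(
        default_factory=lambda: {
            "enabled": True,
            "max_iterations": 20,
            "alpha": 0.01,
            "n_trees": 300,
        }
    )
    forest: dict = dataclasses.field(
        default_factory=lambda: {"n_trees": 1000, "class_weights": "inverse_frequency"}
    )
    prediction: dict = dataclasses.field(
        default_factory=lambda: {
            "missing_policy": "impute_knn",
            "max_missing_fraction": 0.75,
        }
    )

    def __post_init__(self) -> None:
        if self.simulation is None and (self.expression is None or self.annotation is None):
            raise ValueError(
                "config must provide either a simulation block or "
                "expression + annotation paths"
            )
        for section in ("split", "genes", "rules", "boruta", "forest", "prediction"):
            value = getattr(self, section)
            unknown = set(value) - _SECTION_KEYS[section]
            if unknown:
                raise ValueError(f"unknown keys in config section {section}: {sorted(unknown)}")

    @staticmethod
    def from_dict(raw: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _SECTION_KEYS[""]
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        defaults = PipelineConfig.__dataclass_fields__
        merged: dict[str, Any] = {}
        for key, val in raw.items():
            default = defaults[key].default_factory() if defaults[key].default_factory is not dataclasses.MISSING else defaults[key].default  # type: ignore[misc]
            if isinstance(default, dict) and isinstance(val, Mapping):
                merged[key] = {**default, **val}
            else:
                merged[key] = val
        return PipelineConfig(**merged)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return PipelineConfig.from_dict(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full workflow; returns the run manifest (also written).

    Artifacts written under ``out_dir``: filtered expression + annotation,
    selected rules TSV, ``model.json``, held-out ``scores.tsv`` and
    ``report.json``, optional query ``query_scores.tsv``, ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seeds = _stage_seeds(config.seed)
    log: list[dict] = []

    def stage(name: str) -> None:
        log.append({"stage": name, "elapsed_s": round(time.time() - t0, 3)})

    # 1. inputs
    if config.simulation is not None:
        sim = SimulationConfig(seed=seeds[0], **config.simulation)
        expr, ann, _ = simulate_bulk(sim)
    else:
        expr = read_expression(config.expression)
        ann = read_annotation(config.annotation)
    stage("load")

    # 2. prevalence filter
    expr = filter_genes_by_prevalence(expr, config.prevalence_threshold)
    expr.to_tsv(out / "expression.filtered.tsv")
    write_annotation(ann, out / "annotation.tsv")
    stage("filter")

    # 3. split
    split = SplitSpec(train_fraction=config.split["train_fraction"], seed=seeds[1])
    train_ids, test_ids = stratified_split(ann, split)
    train_expr = expr.subset_samples(train_ids)
    test_expr = expr.subset_samples(test_ids)
    ann_idx = ann.set_index("sample_id", drop=False)
    train_ann = ann_idx.loc[train_ids].reset_index(drop=True)
    test_ann = ann_idx.loc[test_ids].reset_index(drop=True)
    stage("split")

    # 4. gene ranking and rule construction on the training partition
    granking = rank_genes(
        train_expr, train_ann, scheme="both", n_trees=config.genes["n_trees"], seed=seeds[2]
    )
    genes, _ = select_top_genes(
        granking,
        n_altogether=config.genes["n_altogether"],
        n_per_class=config.genes["n_per_class"],
    )
    rules = generate_rules(genes)
    rm_train = evaluate_rules(train_expr.subset_genes(sorted(set(genes))), rules)
    stage("rank_genes")

    rranking = rank_rules(
        rm_train,
        train_ann,
        scheme="both",
        class_weights=config.rules["class_weights"],
        n_trees=config.rules["n_trees"],
        seed=seeds[3],
    )
    selection = select_rules(
        rranking,
        n_altogether=config.rules["n_altogether"],
        n_per_class=config.rules["n_per_class"],
        gene_repetition_cap=config.rules["gene_repetition_cap"],
    )
    selection.to_tsv(out / "rules.selected.tsv")
    rm_sel = rm_train.subset(selection.rules)
    stage("rank_rules")

    # 5. Boruta pruning
    if config.boruta["enabled"]:
        pruned = boruta_prune(
            rm_sel,
            train_ann,
            max_iterations=config.boruta["max_iterations"],
            alpha=config.boruta["alpha"],
            n_trees=config.boruta["n_trees"],
            seed=seeds[4],
        )
        rm_final = rm_sel.subset(pruned.kept_rules)
    else:
        rm_final = rm_sel
    stage("boruta")

    # 6. final forest
    model = train_forest(
        rm_final,
        train_ann,
        n_trees=config.forest["n_trees"],
        class_weights=config.forest["class_weights"],
        seed=seeds[5],
    )
    model.to_json(out / "model.json")
    stage("train")

    # 7. held-out evaluation
    pred = predict_scores(
        model,
        test_expr,
        missing_policy=config.prediction["missing_policy"],
        max_missing_fraction=config.prediction["max_missing_fraction"],
    )
    table = score_table(pred, test_ann)
    table.to_csv(out / "scores.tsv", sep="\t", index=False)
    hard = pred.scores.idxmax(axis=1)
    truth = test_ann.set_index("sample_id")["class_label"].loc[pred.scores.index]
    report = confusion_report(truth.tolist(), hard.tolist())
    report.to_json(out / "report.json")
    stage("evaluate")

    # 8. optional external query set
    if config.query is not None:
        q = read_expression(config.query)
        qscores = predict_scores(
            model,
            q,
            missing_policy=config.prediction["missing_policy"],
            max_missing_fraction=config.prediction["max_missing_fraction"],
        )
        score_table(qscores).to_csv(out / "query_scores.tsv", sep="\t", index=False)
        stage("query")

    artifacts = sorted(p for p in out.glob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_final_rules": len(model.rules),
        "held_out_accuracy": report.accuracy,
        "checksums": {p.name: _sha256(p) for p in artifacts},
        "stages": log,
        "finished_unix_time": time.time(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_demo(seed: int, out_dir: str | Path) -> Path:
    """Write a complete, deterministic demo workspace.

    Contents: a 5-class, 5-study imbalanced bulk cohort (TSV + annotation), a
    50/50 astrocyte+microglia mixture query set, toy two-reference FASTA
    files with a shared rRNA-like segment plus simulated FASTQ reads, and a
    ready-to-run ``config.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    sim = SimulationConfig(seed=seeds[0])
    expr, ann, profiles = simulate_bulk(sim)
    expr.to_tsv(out / "expression.tsv")
    write_annotation(ann, out / "annotation.tsv")
    mix = simulate_mixture(
        profiles,
        MixtureSpec(("astrocyte", "microglia"), (0.5, 0.5)),
        n_samples=12,
        seed=seeds[1],
        config=sim,
    )
    mix.to_tsv(out / "query_mixture.tsv")
    ref_a, ref_b, shared = make_read_origin_refs(seeds[2])
    write_fasta(ref_a, out / "ref_a.fasta")
    write_fasta(ref_b, out / "ref_b.fasta")
    write_fasta(shared, out / "rrna.fasta")
    reads = simulate_reads(
        {"a": {"refA_unique": ref_a["refA_unique"]},
         "b": {"refB_unique": ref_b["refB_unique"]},
         "shared": shared},
        {"a": 600, "b": 300, "shared": 400},
        read_len=100,
        error_rate=0.01,
        seed=seeds[3],
    )
    write_fastq(reads, out / "reads.fastq")
    cfg = {
        "seed": int(seed),
        "expression": str(out / "expression.tsv"),
        "annotation": str(out / "annotation.tsv"),
        "query": str(out / "query_mixture.tsv"),
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    return out
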