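"""Pipeline orchestration: configuration, staging, and the run manifest.

A single YAML configuration drives the full chain

    simulate (optional) -> diffexpr -> union -> coexpression
                        -> enrichment -> pivot

on synthetic or user-supplied inputs.  Any leading stage can be skipped by
supplying its input files instead.  Every run writes a ``manifest.json``
recording the configuration snapshot, the seed, the package version and a
SHA-256 digest of every stage input and output, so a run is reproducible
from the manifest plus the files it digests.  Wall-clock stage timings go to
the log only, keeping the manifest byte-identical across repeated seeded
runs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__, coexpression, diffexpr, enrichment, io, pivot
from .enrichment import GeneSetCollection
from .pivot import RegulatorNetwork
from .synthetic import ExpressionDataset, GroundTruth, SimulationConfig, simulate_all

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration fails schema validation."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

_SCHEMA: dict[str, dict[str, type | tuple[type, ...]]] = {
    "simulate": {f: object for f in SimulationConfig.__dataclass_fields__},
    "inputs": {
        "expression": str, "sample_sheet": str, "gene_sets": str,
        "edges": str, "gene_list": str, "ground_truth": str,
    },
    "diffexpr": {"q_max": float, "fc_min": float, "contrasts": list},
    "coexpression": {
        "signed": bool, "candidate_powers": list, "r2_target": float,
        "cut_height": (float, type(None)), "cut_fraction": float,
        "min_module_size": int, "eigengene_dissim_max": float,
    },
    "enrichment": {
        "p_max": float, "q_max": float, "min_set_size": int,
        "max_set_size": int, "universe_policy": str,
    },
    "pivot": {
        "score_min": float, "alpha": float, "min_targets": int,
        "universe_policy": str,
    },
}

_TOP_KEYS = {"seed", *_SCHEMA}


@dataclass
class PipelineConfig:
    """Validated run configuration with per-stage defaults.

    All method constants are configurable; the defaults follow the study
    conventions: differential calls at BH q < 0.05 and |log2FC| >= 1,
    enrichment at p < 0.05 and q < 0.05, ncRNA interaction score > 0.5, and
    pivots at unadjusted p < 0.01 with the >= 2-target gate.
    """

    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    diffexpr: dict[str, Any] = field(default_factory=lambda: {
        "q_max": 0.05, "fc_min": 1.0,
        "contrasts": [["normal", "tumor"], ["normal", "paracancer"]],
    })
    coexpression: dict[str, Any] = field(default_factory=lambda: {
        "signed": False, "candidate_powers": list(range(1, 21)),
        "r2_target": 0.8, "cut_height": None, "cut_fraction": 0.99,
        "min_module_size": 30, "eigengene_dissim_max": 0.25,
    })
    enrichment: dict[str, Any] = field(default_factory=lambda: {
        "p_max": 0.05, "q_max": 0.05, "min_set_size": 5,
        "max_set_size": 2000, "universe_policy": "intersection",
    })
    pivot: dict[str, Any] = field(default_factory=lambda: {
        "score_min": 0.5, "alpha": 0.01, "min_targets": 2,
        "universe_policy": "modules",
    })

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        problems = validate_config_dict(raw)
        if problems:
            raise ConfigError("; ".join(problems))
        cfg = cls()
        cfg.seed = int(raw.get("seed", 0))
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", cfg.seed)
            cfg.simulate = SimulationConfig.from_dict(sim)
            cfg.simulate.validate()
        for section in ("diffexpr", "coexpression", "enrichment", "pivot"):
            if section in raw and raw[section] is not None:
                merged = dict(getattr(cfg, section))
                merged.update(raw[section])
                setattr(cfg, section, merged)
        cfg.inputs = dict(raw.get("inputs") or {})
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def snapshot(self) -> dict:
        return {
            "seed": self.seed,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "inputs": dict(sorted(self.inputs.items())),
            "diffexpr": self.diffexpr,
            "coexpression": self.coexpression,
            "enrichment": self.enrichment,
            "pivot": self.pivot,
        }


def validate_config_dict(raw: Mapping[str, Any]) -> list[str]:
    """Schema check; returns a list of human-readable problems (empty = ok)."""
    problems: list[str] = []
    if not isinstance(raw, Mapping):
        return ["configuration root must be a mapping"]
    for key in raw:
        if key not in _TOP_KEYS:
            problems.append(f"unknown top-level key {key!r}")
    if "seed" in raw and not isinstance(raw["seed"], int):
        problems.append("seed must be an integer")
    for section, fields in _SCHEMA.items():
        sub = raw.get(section)
        if sub is None:
            continue
        if not isinstance(sub, Mapping):
            problems.append(f"section {section!r} must be a mapping")
            continue
        for key, value in sub.items():
            if key not in fields:
                problems.append(f"unknown key {section}.{key}")
                continue
            expected = fields[key]
            if expected is object or value is None:
                continue
            if expected is float and isinstance(value, int):
                continue
            if not isinstance(value, expected):
                problems.append(
                    f"{section}.{key} has type {type(value).__name__}")
    return problems


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seed, per-stage file digests."""

    config: dict
    seed: int
    version: str = __version__
    stages: dict[str, dict[str, dict[str, str]]] = field(default_factory=dict)

    def record(self, stage: str, role: str, path: Path) -> None:
        entry = self.stages.setdefault(stage, {"inputs": {}, "outputs": {}})
        entry[role][path.name] = io.sha256_file(path)

    def write(self, path: str | Path) -> Path:
        return io.write_json({
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "stages": self.stages,
        }, path)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class _Stage:
    """Context manager naming the failing stage and logging its duration."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            log.error("stage %s: failed after %.2fs", self.name, dt)
            raise PipelineError(f"stage '{self.name}' failed: {exc}") from exc
        log.info("stage %s: done in %.2fs", self.name, dt)
        return False


def _require_input(cfg: PipelineConfig, key: str) -> Path:
    if key not in cfg.inputs:
        raise FileNotFoundError(f"no '{key}' input configured and simulation disabled")
    p = Path(cfg.inputs[key])
    if not p.exists():
        raise FileNotFoundError(f"missing input file: {p}")
    return p


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute the configured stages, writing all tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.snapshot(), config.seed)

    # --- simulate or load -------------------------------------------------
    truth: GroundTruth | None = None
    with _Stage("simulate" if config.simulate else "load_inputs"):
        if config.simulate:
            dataset, genesets, edges, truth = simulate_all(config.simulate)
            expr_p = outdir / "expression.tsv"
            sheet_p = outdir / "samples.tsv"
            dataset.write(expr_p, sheet_p)
            gmt_p = io.write_gmt(genesets, outdir / "gene_sets.gmt")
            edges_p = io.write_edges(edges, outdir / "edges.tsv")
            truth_p = truth.to_json(outdir / "ground_truth.json")
            collection = GeneSetCollection.from_dict(genesets)
            network = RegulatorNetwork(edges)
            for p in (expr_p, sheet_p, gmt_p, edges_p, truth_p):
                manifest.record("simulate", "outputs", p)
        else:
            expr_p = _require_input(config, "expression")
            sheet_p = _require_input(config, "sample_sheet")
            gmt_p = _require_input(config, "gene_sets")
            edges_p = _require_input(config, "edges")
            dataset = ExpressionDataset.read(expr_p, sheet_p)
            collection = GeneSetCollection.from_gmt(gmt_p)
            network = RegulatorNetwork.from_tsv(edges_p)
            for p in (expr_p, sheet_p, gmt_p, edges_p):
                manifest.record("load_inputs", "inputs", p)

    # --- differential expression + union ---------------------------------
    if "gene_list" in config.inputs:
        with _Stage("gene_list"):
            gl_path = _require_input(config, "gene_list")
            merged_genes = list(io.read_table(gl_path)["gene"].astype(str))
            manifest.record("gene_list", "inputs", gl_path)
    else:
        with _Stage("diffexpr"):
            de = config.diffexpr
            sets = []
            for i, (ga, gb) in enumerate(de["contrasts"], start=1):
                res = diffexpr.call_differential(dataset, ga, gb,
                                                 de["q_max"], de["fc_min"])
                p = io.write_table(res.table.reset_index(names="gene"),
                                   outdir / f"contrast{i}_{ga}_vs_{gb}.tsv")
                manifest.record("diffexpr", "outputs", p)
                sets.append(res.differential_genes)
            merged = diffexpr.union_differential(*sets[:2]) if len(sets) >= 2 \
                else diffexpr.union_differential(sets[0], [])
            p = io.write_table(merged.table.reset_index(), outdir / "merged_genes.tsv")
            manifest.record("diffexpr", "outputs", p)
            merged_genes = merged.genes

    # --- coexpression modules ---------------------------------------------
    with _Stage("coexpression"):
        cx = config.coexpression
        sub = dataset.subset_genes(merged_genes)
        if len(sub.genes) < 2:
            raise ValueError(f"only {len(sub.genes)} analysis genes; need >= 2")
        result = coexpression.detect_modules(
            sub, signed=cx["signed"],
            candidate_powers=tuple(cx["candidate_powers"]),
            r2_target=cx["r2_target"], cut_height=cx["cut_height"],
            cut_fraction=cx["cut_fraction"],
            min_module_size=cx["min_module_size"],
            eigengene_dissim_max=cx["eigengene_dissim_max"])
        partition = result.partition
        assign = partition.to_frame().merge(
            result.hubs[["gene", "kME", "is_hub"]], on="gene", how="left")
        paths = [
            io.write_table(assign, outdir / "modules.tsv"),
            io.write_table(result.power.table, outdir / "scale_free.tsv"),
            io.write_table(result.eigengene_set.profiles.reset_index(names="module"),
                           outdir / "eigengenes.tsv"),
            io.write_table(result.module_trait, outdir / "module_trait.tsv"),
        ]
        for p in paths:
            manifest.record("coexpression", "outputs", p)

    # --- enrichment --------------------------------------------------------
    with _Stage("enrichment"):
        en = config.enrichment
        table = enrichment.enrich_modules(
            partition, collection, universe_policy=en["universe_policy"],
            measured_genes=sub.genes, p_max=en["p_max"], q_max=en["q_max"],
            min_set_size=en["min_set_size"], max_set_size=en["max_set_size"])
        p = io.write_table(table, outdir / "enrichment.tsv")
        manifest.record("enrichment", "outputs", p)

    # --- pivots -------------------------------------------------------------
    with _Stage("pivot"):
        pv = config.pivot
        filtered = pivot.filter_edges_by_score(network, pv["score_min"])
        if partition.n_modules >= 1:
            pairs, summary = pivot.scan_pivots(
                filtered, partition, alpha=pv["alpha"],
                min_targets=pv["min_targets"],
                universe_policy=pv["universe_policy"],
                measured_genes=dataset.genes)
            tallies = pivot.class_tallies(pairs)
        else:
            import pandas as pd
            pairs = pd.DataFrame(columns=pivot.PIVOT_COLUMNS)
            summary = pd.DataFrame(columns=["regulator", "class",
                                            "n_pivot_modules", "modules", "core"])
            tallies = pivot.class_tallies(pairs)
        for name, df in (("pivots.tsv", pairs), ("pivot_summary.tsv", summary),
                         ("pivot_class_tallies.tsv", tallies)):
            p = io.write_table(df, outdir / name)
            manifest.record("pivot", "outputs", p)

    manifest_p = manifest.write(outdir / "manifest.json")
    log.info("manifest written to %s", manifest_p)
    return manifest


# ---------------------------------------------------------------------------
# input validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    checks: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(paths: Mapping[str, str | Path]) -> ValidationReport:
    """Structural checks on an input bundle without mutating anything.

    ``paths`` may contain: expression, sample_sheet, gene_sets, edges.
    Reports row/column counts and cross-file gene-namespace overlap.
    """
    rep = ValidationReport()
    expr_genes: set[str] = set()
    expr = None
    if "expression" in paths:
        try:
            expr = io.read_expression(paths["expression"])
            expr_genes = set(expr.index)
            rep.checks.append(
                f"expression: {expr.shape[0]} genes x {expr.shape[1]} samples")
        except Exception as e:
            rep.errors.append(f"expression: {e}")
    if "sample_sheet" in paths:
        try:
            sheet = io.read_sample_sheet(paths["sample_sheet"])
            rep.checks.append(f"sample_sheet: {len(sheet)} samples, "
                              f"groups={sorted(sheet['group'].unique())}")
            if expr is not None and list(expr.columns) != list(sheet.index):
                rep.warnings.append("sample sheet rows do not match expression columns")
        except Exception as e:
            rep.errors.append(f"sample_sheet: {e}")
    if "gene_sets" in paths:
        try:
            sets = io.read_gmt(paths["gene_sets"])
            members = set().union(*sets.values()) if sets else set()
            rep.checks.append(f"gene_sets: {len(sets)} sets, {len(members)} genes")
            if expr_genes:
                pct = 100.0 * len(members & expr_genes) / max(1, len(members))
                rep.checks.append(f"gene_sets: {pct:.0f}% member overlap with expression")
                if pct == 0:
                    rep.warnings.append("0% gene-set overlap with expression genes")
        except Exception as e:
            rep.errors.append(f"gene_sets: {e}")
    if "edges" in paths:
        try:
            edges = io.read_edges(paths["edges"])
            targets = set(edges["target"])
            rep.checks.append(f"edges: {len(edges)} edges, "
                              f"{edges['regulator'].nunique()} regulators")
            if expr_genes:
                pct = 100.0 * len(targets & expr_genes) / max(1, len(targets))
                rep.checks.append(f"edges: {pct:.0f}% target overlap with expression")
                if pct == 0:
                    rep.warnings.append("0% target overlap with expression genes")
        except Exception as e:
            rep.errors.append(f"edges: {e}")
    return rep
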