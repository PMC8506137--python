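"""Synthetic data with planted ground truth.

Generates the three input kinds the pipeline consumes — a log2 expression
matrix with group structure, a gene-set collection, and a scored
regulator->target network — from a single seeded configuration, together
with a :class:`GroundTruth` record of everything that was planted.  Every
downstream stage therefore has a recovery test against known truth.

The expression model is a one-factor-per-module Gaussian block model: each
module m has a per-sample latent factor ``f_m ~ N(0, 1)`` and a member gene
g of module m takes the value

    x_gs = baseline_g + a * f_m(s) + delta * de_gs + eps,   eps ~ N(0, sigma^2)

where ``a`` is the factor loading, ``sigma`` the residual noise SD (log2
units), and ``de_gs`` indicates a planted differential-expression shift of
``delta`` log2 units in the affected group's samples.  Background genes are
baseline plus noise.  The implied within-module Pearson correlation is
``a^2 / (a^2 + sigma^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io


class SimulationError(ValueError):
    """Invalid simulation configuration or request."""


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the planted-structure generator.

    The default design mirrors a three-arm tissue study (normal liver,
    tumor-adjacent ("paracancer") tissue, tumor) with three samples per arm.
    Tests that need statistical power use larger groups.
    """

    n_genes: int = 2000
    group_sizes: tuple[int, ...] = (3, 3, 3)
    group_names: tuple[str, ...] = ("normal", "paracancer", "tumor")
    module_sizes: tuple[int, ...] = (50, 50, 50, 50)
    factor_loading: float = 0.8      # a, unitless in (0, 1]
    noise_sd: float = 0.6            # sigma, log2-expression units
    baseline_mean: float = 8.0       # log2 units
    baseline_sd: float = 1.0
    de_effect: float = 2.0           # delta, log2-fold-change units
    de_fraction_per_module: float | tuple[float, ...] = 0.8
    background_de_fraction: float = 0.05
    # gene sets
    geneset_jaccard: float = 0.8
    n_decoy_sets: int = 20
    decoy_set_size: int = 50
    # regulator network
    n_regulators: int = 40
    n_pivots: int = 8
    targets_per_regulator: int = 10
    pivot_enrichment: float = 0.8    # fraction of a planted pivot's targets in its module
    score_threshold_mass: float = 0.9  # fraction of planted ncRNA edge scores above 0.5
    ncrna_fraction: float = 0.5
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes)

    def de_fractions(self) -> tuple[float, ...]:
        f = self.de_fraction_per_module
        if isinstance(f, (int, float)):
            return (float(f),) * self.n_modules
        if len(f) != self.n_modules:
            raise SimulationError(
                f"de_fraction_per_module has {len(f)} entries for {self.n_modules} modules")
        return tuple(float(x) for x in f)

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise SimulationError("sum(module_sizes) exceeds n_genes")
        if any(s < 1 for s in self.module_sizes):
            raise SimulationError("all module sizes must be >= 1")
        if any(g < 2 for g in self.group_sizes):
            raise SimulationError("every group needs >= 2 samples (variance undefined below)")
        if len(self.group_names) != len(self.group_sizes):
            raise SimulationError("group_names and group_sizes disagree in length")
        if not (0 < self.factor_loading <= 1):
            raise SimulationError("factor_loading must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")
        for name in ("pivot_enrichment", "score_threshold_mass", "ncrna_fraction",
                     "background_de_fraction", "geneset_jaccard"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SimulationError(f"{name} must lie in [0, 1]")
        if any(not (0 <= f <= 1) for f in self.de_fractions()):
            raise SimulationError("de_fraction_per_module entries must lie in [0, 1]")
        if self.targets_per_regulator > self.n_genes:
            raise SimulationError("targets_per_regulator exceeds the gene universe")
        if self.decoy_set_size > self.n_genes:
            raise SimulationError("decoy_set_size exceeds the gene universe")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("group_sizes", "group_names", "module_sizes"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("de_fraction_per_module"), list):
            d["de_fraction_per_module"] = tuple(d["de_fraction_per_module"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by output identifiers."""

    module_of: dict[str, int] = field(default_factory=dict)  # gene -> label, 0 = background
    de_genes: dict[str, list[str]] = field(default_factory=dict)  # contrast -> genes
    enriched_sets: dict[str, int] = field(default_factory=dict)   # set name -> module label
    geneset_sizes: dict[str, int] = field(default_factory=dict)
    pivots: list[tuple[str, int]] = field(default_factory=list)   # (regulator, module)
    pivot_class: dict[str, str] = field(default_factory=dict)

    def module_genes(self, label: int) -> list[str]:
        return sorted(g for g, m in self.module_of.items() if m == label)

    def validate(self) -> None:
        labels = set(self.module_of.values())
        for reg, mod in self.pivots:
            if mod not in labels:
                raise SimulationError(f"planted pivot {reg} references missing module {mod}")

    def to_json(self, path: str | Path) -> Path:
        return io.write_json({
            "module_of": self.module_of,
            "de_genes": self.de_genes,
            "enriched_sets": self.enriched_sets,
            "geneset_sizes": self.geneset_sizes,
            "pivots": [[r, m] for r, m in self.pivots],
            "pivot_class": self.pivot_class,
        }, path)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = io.read_json(path)
        return cls(
            module_of={g: int(m) for g, m in d["module_of"].items()},
            de_genes={k: list(v) for k, v in d["de_genes"].items()},
            enriched_sets={k: int(v) for k, v in d["enriched_sets"].items()},
            geneset_sizes={k: int(v) for k, v in d["geneset_sizes"].items()},
            pivots=[(r, int(m)) for r, m in d["pivots"]],
            pivot_class=dict(d["pivot_class"]),
        )


@dataclass
class ExpressionDataset:
    """A log2 expression matrix (genes x samples) with its sample design.

    ``samples`` is indexed by sample id and carries a ``group`` column plus
    one 0/1 ``trait_<group>`` indicator column per group.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("expression columns and sample sheet rows disagree")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def group_samples(self, group: str) -> list[str]:
        hits = self.samples.index[self.samples["group"] == group]
        if len(hits) == 0:
            raise KeyError(f"unknown group label: {group!r}")
        return list(hits)

    def traits(self) -> pd.DataFrame:
        cols = [c for c in self.samples.columns if c.startswith("trait_")]
        return self.samples[cols].astype(float)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionDataset(self.values.loc[keep], self.samples)

    def write(self, expr_path: str | Path, sheet_path: str | Path) -> None:
        io.write_expression(self.values, expr_path)
        io.write_sample_sheet(self.samples, sheet_path)

    @classmethod
    def read(cls, expr_path: str | Path, sheet_path: str | Path) -> "ExpressionDataset":
        return cls(io.read_expression(expr_path), io.read_sample_sheet(sheet_path))


# ---------------------------------------------------------------------------
# RNG plumbing: one root seed, named per-stage streams
# ---------------------------------------------------------------------------

_STAGE_OFFSETS = {"expression": 0, "genesets": 1, "network": 2}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the single run seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[_STAGE_OFFSETS[stage]])


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a block-correlated expression matrix and record the planted truth.

    Contrast 1 ("tumor_vs_normal") shifts a per-module fraction of genes plus a
    background set by ``de_effect`` in tumor samples; contrast 2
    ("paracancer_vs_normal") does the same with independently chosen genes in
    paracancer samples.
    """
    cfg.validate()
    rng = stage_rng(cfg.seed, "expression")

    genes = _gene_names(cfg.n_genes)
    samples, groups = [], []
    for name, size in zip(cfg.group_names, cfg.group_sizes):
        for i in range(1, size + 1):
            samples.append(f"{name}_{i}")
            groups.append(name)
    n_s = len(samples)

    truth = GroundTruth()
    pos = 0
    module_members: list[list[str]] = []
    for label, size in enumerate(cfg.module_sizes, start=1):
        members = genes[pos:pos + size]
        module_members.append(members)
        for g in members:
            truth.module_of[g] = label
        pos += size
    background = genes[pos:]
    for g in background:
        truth.module_of[g] = 0

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    x = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_s))

    factors = rng.standard_normal((cfg.n_modules, n_s))
    gene_index = {g: i for i, g in enumerate(genes)}
    for m, members in enumerate(module_members):
        rows = [gene_index[g] for g in members]
        x[rows, :] += cfg.factor_loading * factors[m]

    # planted differential expression: one shifted group per contrast
    contrasts = {
        "tumor_vs_normal": cfg.group_names[-1],
        "paracancer_vs_normal": cfg.group_names[1] if len(cfg.group_names) > 2 else None,
    }
    group_arr = np.array(groups)
    fracs = cfg.de_fractions()
    for contrast, shifted_group in contrasts.items():
        if shifted_group is None:
            continue
        cols = np.flatnonzero(group_arr == shifted_group)
        chosen: list[str] = []
        for m, members in enumerate(module_members):
            k = int(round(fracs[m] * len(members)))
            if k:
                chosen.extend(rng.choice(members, size=k, replace=False))
        k_bg = int(round(cfg.background_de_fraction * len(background)))
        if k_bg:
            chosen.extend(rng.choice(background, size=k_bg, replace=False))
        rows = [gene_index[g] for g in chosen]
        x[np.ix_(rows, cols)] += cfg.de_effect
        truth.de_genes[contrast] = sorted(chosen)

    values = pd.DataFrame(x, index=genes, columns=samples)
    sheet = pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample"))
    for name in cfg.group_names:
        sheet[f"trait_{name}"] = (sheet["group"] == name).astype(int)
    truth.validate()
    return ExpressionDataset(values, sheet), truth


def simulate_genesets(cfg: SimulationConfig, truth: GroundTruth,
                      rng: np.random.Generator | None = None) -> dict[str, list[str]]:
    """Gene sets: one planted set per module at the configured Jaccard overlap,
    plus uniformly drawn decoy sets.  Updates ``truth`` in place."""
    cfg.validate()
    rng = rng if rng is not None else stage_rng(cfg.seed, "genesets")
    universe = sorted(truth.module_of)
    labels = sorted({m for m in truth.module_of.values() if m > 0})
    sets: dict[str, list[str]] = {}
    for label in labels:
        members = truth.module_genes(label)
        m = len(members)
        J = cfg.geneset_jaccard
        # |S| = m, |S & M| = o solves o / (2m - o) = J
        o = int(round(2 * m * J / (1 + J))) if J > 0 else 0
        o = min(o, m)
        inside = list(rng.choice(members, size=o, replace=False)) if o else []
        outside_pool = sorted(set(universe) - set(members))
        n_out = m - o
        if n_out > len(outside_pool):
            raise SimulationError("requested set size exceeds the available universe")
        outside = list(rng.choice(outside_pool, size=n_out, replace=False)) if n_out else []
        name = f"SET_M{label}"
        sets[name] = sorted(inside + outside)
        truth.enriched_sets[name] = label
        truth.geneset_sizes[name] = m
    if cfg.decoy_set_size > len(universe):
        raise SimulationError("decoy_set_size exceeds the gene universe")
    for i in range(1, cfg.n_decoy_sets + 1):
        name = f"DECOY_{i:03d}"
        sets[name] = sorted(rng.choice(universe, size=cfg.decoy_set_size, replace=False))
        truth.geneset_sizes[name] = cfg.decoy_set_size
    return sets


def simulate_regulator_network(cfg: SimulationConfig, truth: GroundTruth,
                               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Bipartite regulator->target edges with planted pivots.

    Planted pivots draw ``pivot_enrichment`` of their targets from their
    assigned module and the rest uniformly; decoys draw all targets uniformly.
    ncRNA edges get scores with ``score_threshold_mass`` above 0.5; TF edges
    carry score 1 (curated-style, unscored).  Updates ``truth`` in place.
    """
    cfg.validate()
    rng = rng if rng is not None else stage_rng(cfg.seed, "network")
    universe = sorted(truth.module_of)
    if cfg.targets_per_regulator > len(universe):
        raise SimulationError("targets_per_regulator exceeds the gene universe")
    labels = sorted({m for m in truth.module_of.values() if m > 0})
    if cfg.n_pivots > 0 and not labels:
        raise SimulationError("planted pivots require at least one module in the truth")

    rows = []
    for i in range(cfg.n_regulators):
        is_pivot = i < cfg.n_pivots
        cls = "ncRNA" if rng.random() < cfg.ncrna_fraction else "TF"
        name = f"{'PIV' if is_pivot else 'REG'}_{i + 1:03d}"
        if is_pivot:
            module = labels[i % len(labels)]
            members = truth.module_genes(module)
            k_in = min(int(round(cfg.pivot_enrichment * cfg.targets_per_regulator)),
                       len(members))
            inside = list(rng.choice(members, size=k_in, replace=False))
            pool = sorted(set(universe) - set(inside))
            rest = list(rng.choice(pool, size=cfg.targets_per_regulator - k_in,
                                   replace=False))
            targets = inside + rest
            truth.pivots.append((name, module))
            truth.pivot_class[name] = cls
        else:
            targets = list(rng.choice(universe, size=cfg.targets_per_regulator,
                                      replace=False))
        for t in targets:
            if cls == "ncRNA":
                if rng.random() < cfg.score_threshold_mass:
                    score = rng.uniform(0.5, 1.0)
                else:
                    score = rng.uniform(0.0, 0.5)
            else:
                score = 1.0
            rows.append((name, t, score, cls))
    truth.validate()
    return pd.DataFrame(rows, columns=["regulator", "target", "score", "class"])


def simulate_all(cfg: SimulationConfig) -> tuple[ExpressionDataset, dict[str, list[str]],
                                                 pd.DataFrame, GroundTruth]:
    """Run all three generators off one seed; returns dataset, gene sets,
    regulator edges and the combined ground truth."""
    dataset, truth = simulate_expression(cfg)
    sets = simulate_genesets(cfg, truth)
    edges = simulate_regulator_network(cfg, truth)
    return dataset, sets, edges, truth
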