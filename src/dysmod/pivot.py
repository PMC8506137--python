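"""Pivot analysis: ncRNA and TF regulators over-targeting coexpression modules.

A regulator is tested against a module only when at least two of its targets
fall inside the module; the test is the exact hypergeometric upper tail, and
a tested pair with unadjusted p below alpha (default 0.01) makes the
regulator a *pivot* of that module.  A regulator that is a pivot of two or
more modules is a *core pivot*.  Before testing, ncRNA edges are filtered to
interaction score strictly above a cutoff (default 0.5); TF edges are
curated-style and carry no meaningful score, so they pass unconditionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import io
from .diffexpr import bh_adjust
from .enrichment import hypergeom_sf

log = logging.getLogger(__name__)

REGULATOR_CLASSES = ("ncRNA", "TF")

PIVOT_COLUMNS = ["regulator", "class", "module", "k", "K", "n", "N",
                 "tested", "p_value", "q_value", "is_pivot"]


@dataclass
class RegulatorNetwork:
    """Scored regulator -> target bipartite edges.

    Duplicate (regulator, target) pairs collapse to the maximum score; the
    class (ncRNA or TF) must be constant per regulator.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.edges.copy()
        missing = {"regulator", "target", "score", "class"} - set(df.columns)
        if missing:
            raise ValueError(f"edge table lacks columns: {sorted(missing)}")
        bad = set(df["class"]) - set(REGULATOR_CLASSES)
        if bad:
            raise ValueError(f"unknown regulator class(es): {sorted(bad)}")
        n_cls = df.groupby("regulator")["class"].nunique()
        mixed = n_cls[n_cls > 1]
        if len(mixed):
            raise ValueError(f"regulator(s) with mixed class: {sorted(mixed.index)[:5]}")
        df = (df.sort_values("score")
                .drop_duplicates(["regulator", "target"], keep="last")
                .sort_values(["regulator", "target"])
                .reset_index(drop=True))
        self.edges = df

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def regulators(self) -> list[str]:
        return sorted(self.edges["regulator"].unique())

    def regulator_class(self, regulator: str) -> str:
        return self.edges.loc[self.edges["regulator"] == regulator, "class"].iloc[0]

    def targets_of(self, regulator: str) -> frozenset[str]:
        return frozenset(self.edges.loc[self.edges["regulator"] == regulator, "target"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegulatorNetwork":
        return cls(io.read_edges(path))

    def to_tsv(self, path: str | Path) -> Path:
        return io.write_edges(self.edges, path)


def filter_edges_by_score(network: RegulatorNetwork,
                          score_min: float = 0.5) -> RegulatorNetwork:
    """Keep ncRNA edges with score strictly above ``score_min``; TF edges
    pass unconditionally (curated, unscored)."""
    if not (0 <= score_min <= 1):
        raise ValueError("score_min must lie in [0, 1]")
    df = network.edges
    keep = (df["class"] == "TF") | (df["score"] > score_min)
    return RegulatorNetwork(df[keep].reset_index(drop=True))


@dataclass
class PivotRow:
    regulator: str
    regulator_class: str
    module: int
    k: int               # regulator targets inside the module
    K: int               # regulator targets inside the universe
    n: int               # module size inside the universe
    N: int               # universe size
    tested: bool
    p_value: float | None
    is_pivot: bool = False


UNIVERSE_POLICIES = ("modules", "network", "measured")


def _pivot_universe(network: RegulatorNetwork, partition,
                    universe_policy: str,
                    measured_genes: Iterable[str] | None) -> frozenset[str]:
    if universe_policy not in UNIVERSE_POLICIES:
        raise ValueError(f"unknown universe policy {universe_policy!r}")
    if universe_policy == "modules":
        return frozenset(partition.assigned_genes())
    if universe_policy == "network":
        return frozenset(network.edges["target"])
    if measured_genes is None:
        raise ValueError("universe policy 'measured' needs measured_genes")
    return frozenset(measured_genes)


def pivot_pvalue(regulator_targets: Iterable[str], module_genes: Iterable[str],
                 universe: Iterable[str], min_targets: int = 2,
                 regulator: str = "", regulator_class: str = "ncRNA",
                 module: int = 0) -> PivotRow:
    """Hypergeometric test of one regulator against one module.

    Targets are intersected with the universe before counting; pairs with
    fewer than ``min_targets`` in-module targets are reported untested.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    module_set = frozenset(module_genes)
    if not module_set <= universe:
        module_set = module_set & universe
    targets = frozenset(regulator_targets) & universe
    k = len(targets & module_set)
    K = len(targets)
    n = len(module_set)
    N = len(universe)
    if k < min_targets:
        return PivotRow(regulator, regulator_class, module, k, K, n, N,
                        tested=False, p_value=None)
    p = hypergeom_sf(k, K, n, N)
    return PivotRow(regulator, regulator_class, module, k, K, n, N,
                    tested=True, p_value=p)


def scan_pivots(network: RegulatorNetwork, partition, alpha: float = 0.01,
                min_targets: int = 2, universe_policy: str = "modules",
                measured_genes: Iterable[str] | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every (regulator, module) pair; call pivots at unadjusted
    ``p < alpha``.

    Returns the long-format pair table (with an informational BH ``q_value``
    column over the tested pairs) and a per-regulator summary with the
    core-pivot flag (pivot of >= 2 modules).  Pairs with zero in-module
    targets are omitted from the table; pairs with ``0 < k < min_targets``
    appear untested.
    """
    if partition.n_modules < 1:
        raise ValueError("partition has no modules")
    universe = _pivot_universe(network, partition, universe_policy, measured_genes)
    module_sets = {label: frozenset(partition.module_genes(label)) & universe
                   for label in partition.module_labels}
    by_reg = network.edges.groupby("regulator")
    target_map = {reg: frozenset(sub["target"]) for reg, sub in by_reg}
    class_map = {reg: sub["class"].iloc[0] for reg, sub in by_reg}
    rows: list[PivotRow] = []
    for regulator in network.regulators:
        targets = target_map[regulator]
        cls = class_map[regulator]
        for label in partition.module_labels:
            row = pivot_pvalue(targets, module_sets[label], universe,
                               min_targets, regulator, cls, label)
            if row.k >= 1:
                rows.append(row)
    table = pd.DataFrame(
        [(r.regulator, r.regulator_class, r.module, r.k, r.K, r.n, r.N,
          r.tested, r.p_value if r.tested else np.nan) for r in rows],
        columns=PIVOT_COLUMNS[:-2])
    table["q_value"] = np.nan
    tested_mask = table["tested"].to_numpy(dtype=bool) if len(table) else np.array([], bool)
    if tested_mask.any():
        table.loc[tested_mask, "q_value"] = bh_adjust(
            table.loc[tested_mask, "p_value"].to_numpy())
    table["is_pivot"] = tested_mask & (table["p_value"] < alpha)
    table = table.sort_values(["regulator", "module"]).reset_index(drop=True)

    summ_rows = []
    for regulator in network.regulators:
        sub = table[(table["regulator"] == regulator) & table["is_pivot"]]
        modules = sorted(int(m) for m in sub["module"])
        summ_rows.append((regulator, network.regulator_class(regulator),
                          len(modules), ",".join(map(str, modules)),
                          len(modules) >= 2))
    summary = pd.DataFrame(summ_rows, columns=["regulator", "class",
                                               "n_pivot_modules", "modules",
                                               "core"])
    return table, summary


def class_tallies(table: pd.DataFrame) -> pd.DataFrame:
    """Per-class pivot counts: distinct pivot regulators and significant
    regulator-module pairs for ncRNA and TF separately."""
    rows = []
    for cls in REGULATOR_CLASSES:
        sub = table[(table["class"] == cls) & table["is_pivot"]]
        rows.append((cls, sub["regulator"].nunique(), len(sub)))
    return pd.DataFrame(rows, columns=["class", "n_pivot_regulators",
                                       "n_pivot_pairs"])
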