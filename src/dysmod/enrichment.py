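"""Hypergeometric over-representation of gene lists in annotation gene sets.

The kernel is an exact upper-tail hypergeometric probability evaluated in
log space; the same kernel backs the regulator pivot tests.  Enrichment of a
query (typically one coexpression module) against a GMT collection reports
one row per tested set, BH q-values within each namespace, and a
significance call at the p and q cutoffs (defaults 0.05 / 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import io
from .diffexpr import bh_adjust

log = logging.getLogger(__name__)


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -np.inf
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_sf(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    ``N`` is the universe size, ``K`` the number of marked items, ``n`` the
    draw size, ``k`` the observed overlap.
    """
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N and k >= 0):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    denom = _log_comb(N, n)
    terms = [_log_comb(K, i) + _log_comb(N - K, n - i) - denom
             for i in range(k, min(K, n) + 1)]
    terms = [t for t in terms if np.isfinite(t)]
    if not terms:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(terms))))


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional namespace tag per set."""

    sets: dict[str, frozenset[str]]
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def namespace(self, name: str) -> str:
        return self.namespaces.get(name, "default")

    @classmethod
    def from_gmt(cls, path: str | Path, namespace: str | None = None) -> "GeneSetCollection":
        raw = io.read_gmt(path)
        ns = {name: namespace for name in raw} if namespace else {}
        return cls({name: frozenset(m) for name, m in raw.items()}, ns)

    @classmethod
    def from_dict(cls, sets: Mapping[str, Iterable[str]],
                  namespaces: Mapping[str, str] | None = None) -> "GeneSetCollection":
        return cls({k: frozenset(v) for k, v in sets.items()},
                   dict(namespaces or {}))

    def to_gmt(self, path: str | Path) -> Path:
        return io.write_gmt(self.sets, path)


UNIVERSE_POLICIES = ("collection", "measured", "intersection")

ENRICH_COLUMNS = ["set_name", "namespace", "module", "k", "n", "K", "N",
                  "p_value", "q_value", "significant"]


def resolve_universe(collection: GeneSetCollection, universe_policy: str,
                     measured_genes: Iterable[str] | None) -> frozenset[str]:
    """Background universe under the named policy.

    - ``collection``: union of all collection members;
    - ``measured``: the genes of the analyzed expression matrix;
    - ``intersection`` (default policy of :func:`enrich`): both.
    """
    if universe_policy not in UNIVERSE_POLICIES:
        raise ValueError(f"unknown universe policy {universe_policy!r}")
    if universe_policy == "collection":
        return collection.universe
    if measured_genes is None:
        raise ValueError(f"universe policy {universe_policy!r} needs measured_genes")
    measured = frozenset(measured_genes)
    if universe_policy == "measured":
        return measured
    return collection.universe & measured


def enrich(query_genes: Iterable[str], collection: GeneSetCollection,
           universe_policy: str = "intersection",
           measured_genes: Iterable[str] | None = None,
           p_max: float = 0.05, q_max: float = 0.05,
           min_set_size: int = 5, max_set_size: int = 2000,
           module_label: int | str = "", ) -> pd.DataFrame:
    """Over-representation of a query gene list in every collection set.

    Sets are restricted to the universe and filtered to size within
    ``[min_set_size, max_set_size]``; only sets overlapping the query
    (k >= 1) are tested, and BH q-values are computed per namespace over the
    tested sets.  Rows are sorted by p-value then set name.
    """
    query = set(query_genes)
    if not query:
        raise ValueError("empty query")
    universe = resolve_universe(collection, universe_policy, measured_genes)
    q_in = query & universe
    if not q_in:
        log.warning("enrich: query has no overlap with the universe")
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    n = len(q_in)
    N = len(universe)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        K = len(members)
        if not (min_set_size <= K <= max_set_size):
            continue
        k = len(q_in & members)
        if k < 1:
            continue
        p = hypergeom_sf(k, K, n, N)
        rows.append((name, collection.namespace(name), module_label, k, n, K, N, p))
    if not rows:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-2])
    df["q_value"] = np.nan
    for ns in df["namespace"].unique():
        mask = df["namespace"] == ns
        df.loc[mask, "q_value"] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
    df["significant"] = (df["p_value"] < p_max) & (df["q_value"] < q_max)
    return df.sort_values(["p_value", "set_name"]).reset_index(drop=True)


def enrich_modules(partition, collection: GeneSetCollection,
                   universe_policy: str = "intersection",
                   measured_genes: Iterable[str] | None = None,
                   **kwargs) -> pd.DataFrame:
    """Run :func:`enrich` for each module of a partition; long-format table."""
    tables = []
    for label in partition.module_labels:
        genes = partition.module_genes(label)
        tab = enrich(genes, collection, universe_policy, measured_genes,
                     module_label=label, **kwargs)
        tables.append(tab)
    if not tables:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    return pd.concat(tables, ignore_index=True)
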