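"""Differential expression: Welch t contrasts, BH adjustment, set union.

Two group contrasts are called on log2 expression (Welch's unequal-variance
t-test with Satterthwaite degrees of freedom, Benjamini-Hochberg q-values,
and an absolute log2-fold-change floor) and their significant gene sets are
merged into one analysis set with per-gene provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t(values_a, values_b) -> WelchResult:
    """Welch's two-sample t-test on log2 expression values.

    Degenerate inputs (zero variance in both groups) return t=0, p=1 when the
    means agree and p=0 with a degenerate flag when they differ.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    t, df, p, degen = _welch_arrays(a.reshape(1, -1), b.reshape(1, -1))
    return WelchResult(float(t[0]), float(df[0]), float(p[0]), bool(degen[0]))


def _welch_arrays(a: np.ndarray, b: np.ndarray):
    """Vectorized Welch test over rows; returns (t, df, p, degenerate)."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    zero = denom == 0
    equal = np.isclose(ma, mb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / denom
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = np.empty_like(t)
    ok = ~zero
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    # both groups constant
    t[zero & equal] = 0.0
    p[zero & equal] = 1.0
    df[zero] = np.nan
    t[zero & ~equal] = np.sign(mb - ma)[zero & ~equal] * np.inf
    p[zero & ~equal] = 0.0
    degenerate = zero & ~equal
    return t, df, p, degenerate


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    Computed directly as ``min_{j >= i} p_(j) * m / j`` on the sorted
    p-values, so the adjusted values are exactly the step-up quantities
    (agrees with statsmodels' ``fdr_bh`` to floating rounding).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


@dataclass
class ContrastResult:
    """Per-gene statistics for one two-group contrast.

    ``table`` columns: mean_a, mean_b, log2fc (mean_b - mean_a), t_statistic,
    df, p_value, q_value, degenerate, is_differential; indexed by gene.
    """

    group_a: str
    group_b: str
    q_max: float
    fc_min: float
    table: pd.DataFrame
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def differential_genes(self) -> list[str]:
        return sorted(self.table.index[self.table["is_differential"]])


def call_differential(expr: ExpressionDataset, group_a: str, group_b: str,
                      q_max: float = 0.05, fc_min: float = 1.0) -> ContrastResult:
    """Test every gene for differential expression between two sample groups.

    Genes flat across all samples of both groups are dropped before testing
    (they carry no statistical information and would yield undefined
    statistics); the drop is logged and recorded on the result.
    """
    samples_a = expr.group_samples(group_a)
    samples_b = expr.group_samples(group_b)
    if set(samples_a) & set(samples_b):
        raise ValueError("contrast groups share samples")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each contrast group needs >= 2 samples")

    a = expr.values[samples_a].to_numpy(dtype=float)
    b = expr.values[samples_b].to_numpy(dtype=float)
    both = np.concatenate([a, b], axis=1)
    flat = both.std(axis=1) == 0
    dropped = [g for g, f in zip(expr.values.index, flat) if f]
    if dropped:
        log.info("call_differential: dropped %d zero-variance genes", len(dropped))
    keep = ~flat
    genes = expr.values.index[keep]
    t, df, p, degen = _welch_arrays(a[keep], b[keep])
    q = bh_adjust(p)
    lfc = b[keep].mean(axis=1) - a[keep].mean(axis=1)
    table = pd.DataFrame({
        "mean_a": a[keep].mean(axis=1),
        "mean_b": b[keep].mean(axis=1),
        "log2fc": lfc,
        "t_statistic": t,
        "df": df,
        "p_value": p,
        "q_value": q,
        "degenerate": degen,
    }, index=genes)
    table["is_differential"] = (table["q_value"] < q_max) & (np.abs(lfc) >= fc_min)
    return ContrastResult(group_a, group_b, q_max, fc_min, table, dropped)


@dataclass
class MergedGeneSet:
    """Union of two differential gene sets with per-gene provenance."""

    table: pd.DataFrame  # index gene, column 'provenance' in {contrast1, contrast2, both}

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def union_differential(set1, set2) -> MergedGeneSet:
    """Merge two gene sets, flagging each gene's contrast of origin."""
    s1, s2 = set(set1), set(set2)
    rows = []
    for g in sorted(s1 | s2):
        prov = "both" if (g in s1 and g in s2) else ("contrast1" if g in s1 else "contrast2")
        rows.append((g, prov))
    table = pd.DataFrame(rows, columns=["gene", "provenance"]).set_index("gene")
    return MergedGeneSet(table)
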