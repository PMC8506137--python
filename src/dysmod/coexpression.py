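"""Weighted coexpression network construction and module detection.

The workflow follows the WGCNA recipe: Pearson correlation between gene
profiles, soft-thresholding by a power chosen under the scale-free topology
criterion, topological overlap (TOM) as a robust similarity, average-linkage
clustering of ``1 - TOM``, a static tree cut into modules, eigengene-based
merging of near-duplicate modules, and module summaries (eigengenes,
module-trait correlations, kME hub genes).

Modules are labeled by decreasing size with 1..K; label 0 collects
unassigned genes.  A fixed label->color table mirrors the conventional
colored-dendrogram display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .synthetic import ExpressionDataset

log = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-10

# conventional module colors, index 0 = unassigned
MODULE_COLORS = (
    "grey", "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
)


def label_color(label: int) -> str:
    return MODULE_COLORS[label % len(MODULE_COLORS)]


# ---------------------------------------------------------------------------
# correlation, adjacency, scale-free fit
# ---------------------------------------------------------------------------

def correlation_matrix(expr: ExpressionDataset | pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation across samples."""
    values = expr.values if isinstance(expr, ExpressionDataset) else expr
    if values.shape[1] < 3:
        raise ValueError("correlation needs >= 3 samples")
    sd = values.std(axis=1, ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(f"zero-variance gene(s): {', '.join(map(str, flat.index[:5]))}")
    r = np.corrcoef(values.to_numpy(dtype=float))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=values.index, columns=values.index)


@dataclass
class AdjacencyMatrix:
    weights: pd.DataFrame
    beta: int
    signed: bool

    @property
    def genes(self) -> pd.Index:
        return self.weights.index

    def connectivity(self) -> pd.Series:
        """k_i = sum_{j != i} a_ij."""
        w = self.weights.to_numpy()
        return pd.Series(w.sum(axis=1) - np.diag(w), index=self.genes, name="k")


def soft_threshold_adjacency(cor: pd.DataFrame, beta: int,
                             signed: bool = False) -> AdjacencyMatrix:
    """Raise correlations to the soft-thresholding power.

    Unsigned: ``a_ij = |r_ij|^beta``; signed: ``a_ij = ((1 + r_ij)/2)^beta``.
    """
    if int(beta) != beta or beta < 1:
        raise ValueError("beta must be an integer >= 1")
    r = cor.to_numpy(dtype=float)
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(pd.DataFrame(a, index=cor.index, columns=cor.columns),
                           int(beta), signed)


@dataclass
class ScaleFreeFit:
    r_squared: float
    slope: float
    defined: bool
    n_bins_used: int = 0

    @property
    def passes(self) -> bool:
        return self.defined and self.slope < 0


def scale_free_fit(adjacency: AdjacencyMatrix, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit: R^2 of log10(freq) on log10(mean k).

    Connectivities are binned into equal-width bins; empty bins and bins with
    non-positive mean connectivity are unusable.  Fewer than 2 usable bins
    (e.g. all connectivities identical) yields an undefined fit.
    """
    k = adjacency.connectivity().to_numpy()
    if k.size < 2 or np.ptp(k) == 0:
        return ScaleFreeFit(np.nan, np.nan, defined=False)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 2:
        return ScaleFreeFit(np.nan, np.nan, defined=False)
    fit = stats.linregress(xs, ys)
    return ScaleFreeFit(float(fit.rvalue**2), float(fit.slope), True, len(xs))


@dataclass
class PowerSelection:
    beta: int
    achieved_r2: float
    table: pd.DataFrame  # columns beta, r_squared, slope, passes
    target_met: bool


def pick_power(cor: pd.DataFrame, candidate_powers=tuple(range(1, 21)),
               r2_target: float = 0.8, signed: bool = False,
               n_bins: int = 10) -> PowerSelection:
    """Smallest power whose scale-free fit reaches ``r2_target`` with a
    negative slope; falls back (with a warning) to the best-R^2 candidate."""
    candidates = list(candidate_powers)
    if not candidates:
        raise ValueError("candidate_powers is empty")
    rows = []
    chosen = None
    for beta in candidates:
        fit = scale_free_fit(soft_threshold_adjacency(cor, beta, signed), n_bins)
        ok = fit.passes and fit.r_squared >= r2_target
        rows.append((beta, fit.r_squared, fit.slope, ok))
        if ok and chosen is None:
            chosen = (beta, fit.r_squared)
    table = pd.DataFrame(rows, columns=["beta", "r_squared", "slope", "passes"])
    if chosen is None:
        defined = table.dropna(subset=["r_squared"])
        if defined.empty:
            raise ValueError("scale-free fit undefined for every candidate power")
        best = defined.loc[defined["r_squared"].idxmax()]
        log.warning("no candidate power reached scale-free R^2 >= %.2f; "
                    "falling back to beta=%d (R^2=%.3f)",
                    r2_target, int(best["beta"]), best["r_squared"])
        return PowerSelection(int(best["beta"]), float(best["r_squared"]), table, False)
    return PowerSelection(chosen[0], chosen[1], table, True)


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

def tom(adjacency: AdjacencyMatrix) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    ``tom_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_{u != i,j} a_iu a_uj``; the diagonal is set to 1.
    """
    a = adjacency.weights.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a                     # off-diagonal u terms only, since diag(a)=0
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (l + a) / denom
    bad = denom <= 0
    if bad.any():
        log.warning("tom: %d entries with non-positive denominator set to 0", bad.sum())
        t[bad] = 0.0
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adjacency.genes, columns=adjacency.genes)


# ---------------------------------------------------------------------------
# clustering and module assignment
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    merge: np.ndarray          # scipy linkage matrix
    genes: list[str]

    @property
    def max_height(self) -> float:
        return float(self.merge[:, 2].max())


def cluster_genes(dissimilarity: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomerative clustering of a gene dissimilarity."""
    d = dissimilarity.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=SYMMETRY_TOL):
        raise ValueError("dissimilarity must be symmetric")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(z, list(dissimilarity.index))


@dataclass
class ModulePartition:
    """Gene -> module label assignment (0 = unassigned), labels 1..K ordered
    by decreasing module size, ties broken by the smallest member gene id."""

    labels: pd.Series
    cut_height: float
    min_module_size: int

    @property
    def module_labels(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    @property
    def n_modules(self) -> int:
        return len(self.module_labels)

    def module_genes(self, label: int) -> list[str]:
        return sorted(self.labels.index[self.labels == label])

    def assigned_genes(self) -> list[str]:
        return sorted(self.labels.index[self.labels > 0])

    def colors(self) -> pd.Series:
        return self.labels.map(label_color)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.labels.index, "module": self.labels.values,
                             "color": self.colors().values})


def _relabel_by_size(raw: pd.Series, min_module_size: int,
                     cut_height: float) -> ModulePartition:
    sizes = raw.value_counts()
    survivors = [c for c in sizes.index if sizes[c] >= min_module_size]
    # order by decreasing size; ties by smallest member gene id
    def sort_key(c):
        members = raw.index[raw == c]
        return (-sizes[c], min(members))
    survivors.sort(key=sort_key)
    mapping = {c: i + 1 for i, c in enumerate(survivors)}
    labels = raw.map(lambda c: mapping.get(c, 0)).astype(int)
    return ModulePartition(labels, cut_height, min_module_size)


def cut_tree_modules(dendrogram: Dendrogram, cut_height: float | None = None,
                     min_module_size: int = 30,
                     cut_fraction: float = 0.99) -> ModulePartition:
    """Static cut of the dendrogram into modules.

    ``cut_height=None`` cuts at ``cut_fraction`` of the maximum merge height.
    Clusters smaller than ``min_module_size`` become unassigned (label 0).
    """
    if cut_height is None:
        cut_height = cut_fraction * dendrogram.max_height
    raw = fcluster(dendrogram.merge, t=cut_height, criterion="distance")
    series = pd.Series(raw, index=pd.Index(dendrogram.genes, name="gene"))
    return _relabel_by_size(series, min_module_size, float(cut_height))


# ---------------------------------------------------------------------------
# eigengenes, merging, module-trait, hubs
# ---------------------------------------------------------------------------

@dataclass
class EigengeneSet:
    """Per-module representative profiles (unit norm, rows 'M<label>').

    Each eigengene is the leading principal component across samples of the
    gene-standardized module submatrix, sign-oriented to correlate
    non-negatively with the module mean profile.
    """

    profiles: pd.DataFrame              # modules x samples
    variance_explained: pd.Series       # module -> share in [0, 1]
    orientation: pd.Series = field(default=None)  # module -> +-1

    def module_row(self, label: int) -> pd.Series:
        return self.profiles.loc[f"M{label}"]


def _standardize(values: pd.DataFrame) -> np.ndarray:
    x = values.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def eigengenes(expr: ExpressionDataset, partition: ModulePartition) -> EigengeneSet:
    """First principal component per module, on gene-standardized profiles."""
    rows, ve, signs = {}, {}, {}
    for label in partition.module_labels:
        genes = partition.module_genes(label)
        if len(genes) < 2:
            raise ValueError(f"module {label} has < 2 genes")
        x = _standardize(expr.values.loc[genes])
        # SVD of genes x samples: leading right singular vector spans samples
        _, s, vt = np.linalg.svd(x, full_matrices=False)
        e = vt[0]
        e = e / np.linalg.norm(e)
        mean_profile = x.mean(axis=0)
        c = np.corrcoef(e, mean_profile)[0, 1] if mean_profile.std() > 0 else 1.0
        sign = -1.0 if c < 0 else 1.0
        rows[f"M{label}"] = sign * e
        ve[f"M{label}"] = float(s[0] ** 2 / (s**2).sum())
        signs[f"M{label}"] = sign
    profiles = pd.DataFrame(rows, index=expr.values.columns).T
    return EigengeneSet(profiles, pd.Series(ve, name="variance_explained"),
                        pd.Series(signs, name="orientation"))


def merge_close_modules(expr: ExpressionDataset, partition: ModulePartition,
                        eigengene_dissim_max: float = 0.25) -> ModulePartition:
    """Iteratively merge the most-correlated module pair while their
    eigengene dissimilarity ``1 - cor`` stays below the threshold."""
    labels = partition.labels.copy()
    while True:
        current = sorted(set(labels) - {0})
        if len(current) < 2:
            break
        part = ModulePartition(labels, partition.cut_height, partition.min_module_size)
        eg = eigengenes(expr, part)
        prof = eg.profiles.to_numpy()
        cor = np.corrcoef(prof)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= eigengene_dissim_max:
            break
        a = int(eg.profiles.index[i][1:])
        b = int(eg.profiles.index[j][1:])
        labels[labels == max(a, b)] = min(a, b)
    raw = pd.Series(labels, index=partition.labels.index)
    assigned = raw[raw > 0]
    out = _relabel_by_size(assigned, partition.min_module_size, partition.cut_height)
    full = pd.Series(0, index=partition.labels.index, name=partition.labels.name)
    full[out.labels.index] = out.labels
    return ModulePartition(full.astype(int), partition.cut_height,
                           partition.min_module_size)


def module_trait_correlation(eigengene_set: EigengeneSet,
                             traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided Student p (n-2 df) per (module, trait).

    Constant traits yield a flagged row with undefined r and p.
    """
    if list(traits.index) != list(eigengene_set.profiles.columns):
        traits = traits.loc[eigengene_set.profiles.columns]
    n = traits.shape[0]
    rows = []
    for module in eigengene_set.profiles.index:
        e = eigengene_set.profiles.loc[module].to_numpy(dtype=float)
        for trait in traits.columns:
            t_vec = traits[trait].to_numpy(dtype=float)
            if np.std(t_vec) == 0:
                rows.append((module, trait, np.nan, np.nan, True))
                continue
            r = float(np.corrcoef(e, t_vec)[0, 1])
            r = max(-1.0, min(1.0, r))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t_stat = r * np.sqrt((n - 2) / (1.0 - r**2))
                p = float(2.0 * stats.t.sf(abs(t_stat), n - 2))
            rows.append((module, trait, r, p, False))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p", "undefined"])


def hub_genes(expr: ExpressionDataset, partition: ModulePartition,
              eigengene_set: EigengeneSet) -> pd.DataFrame:
    """kME ranking per module: correlation of each member gene with its
    module eigengene; the top gene is the module hub (ties by gene id)."""
    rows = []
    for label in partition.module_labels:
        genes = partition.module_genes(label)
        e = eigengene_set.module_row(label).to_numpy(dtype=float)
        x = expr.values.loc[genes].to_numpy(dtype=float)
        xc = x - x.mean(axis=1, keepdims=True)
        ec = e - e.mean()
        denom = np.sqrt((xc**2).sum(axis=1) * (ec**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            kme = (xc @ ec) / denom
        for g, k in zip(genes, kme):
            rows.append((label, g, float(k)))
    df = pd.DataFrame(rows, columns=["module", "gene", "kME"])
    df = df.sort_values(["module", "kME", "gene"],
                        ascending=[True, False, True]).reset_index(drop=True)
    df["is_hub"] = False
    for label in partition.module_labels:
        idx = df.index[df["module"] == label]
        if len(idx):
            df.loc[idx[0], "is_hub"] = True
    return df


# ---------------------------------------------------------------------------
# one-call pipeline stage
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionResult:
    power: PowerSelection
    partition: ModulePartition
    eigengene_set: EigengeneSet
    module_trait: pd.DataFrame
    hubs: pd.DataFrame
    dendrogram: Dendrogram


def detect_modules(expr: ExpressionDataset,
                   signed: bool = False,
                   candidate_powers=tuple(range(1, 21)),
                   r2_target: float = 0.8,
                   cut_height: float | None = None,
                   cut_fraction: float = 0.99,
                   min_module_size: int = 30,
                   eigengene_dissim_max: float = 0.25) -> CoexpressionResult:
    """Full coexpression stage: correlation -> power -> TOM -> tree -> modules
    -> merge -> eigengenes -> module-trait table -> hubs."""
    cor = correlation_matrix(expr)
    power = pick_power(cor, candidate_powers, r2_target, signed)
    adj = soft_threshold_adjacency(cor, power.beta, signed)
    t = tom(adj)
    dendro = cluster_genes(1.0 - t)
    partition = cut_tree_modules(dendro, cut_height, min_module_size, cut_fraction)
    if partition.n_modules > 1 and eigengene_dissim_max > 0:
        partition = merge_close_modules(expr, partition, eigengene_dissim_max)
    if partition.n_modules == 0:
        log.warning("detect_modules: no module reached min size %d", min_module_size)
        empty = EigengeneSet(pd.DataFrame(columns=expr.values.columns),
                             pd.Series(dtype=float))
        return CoexpressionResult(power, partition, empty,
                                  pd.DataFrame(columns=["module", "trait", "r", "p",
                                                        "undefined"]),
                                  pd.DataFrame(columns=["module", "gene", "kME",
                                                        "is_hub"]),
                                  dendro)
    eg = eigengenes(expr, partition)
    mt = module_trait_correlation(eg, expr.traits())
    hubs = hub_genes(expr, partition, eg)
    return CoexpressionResult(power, partition, eg, mt, hubs, dendro)
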