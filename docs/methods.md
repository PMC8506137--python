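# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions. Nothing here states a result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data model

The generator produces the three inputs the pipeline consumes from one
seeded configuration, with the planted structure recorded in a
`GroundTruth` object.

**Expression.** A one-factor-per-module Gaussian block model on the log2
scale. Module *m* has a latent per-sample factor *f<sub>m</sub>* ~ N(0, 1);
member gene *g* in sample *s* is

> x<sub>gs</sub> = b<sub>g</sub> + a·f<sub>m</sub>(s) + δ·1[g planted DE, s in shifted group] + ε,  ε ~ N(0, σ²)

with baseline b<sub>g</sub> ~ N(8, 1) (typical log2 microarray intensity),
factor loading *a* ∈ (0, 1], and noise σ in log2 units. Background genes
are baseline plus noise. The implied within-module correlation is
a²/(a² + σ²) — the calibration tests check the empirical mean against this
closed form, with a Monte-Carlo tolerance dominated by the factor's
realized-variance noise, SE ≈ (a²σ²/(a²+σ²)²)·√(2/(n−1)).

Differential structure mirrors a two-contrast design: contrast 1 shifts a
per-module fraction of genes (plus a background set) by δ in the
third-group (tumor) samples; contrast 2 shifts independently chosen genes
in the second-group (adjacent-tissue) samples. Trait vectors are the 0/1
group indicators. Default group sizes are 3/3/3, matching the motivating
three-arm design; that size is deliberately underpowered, so tests and the
acceptance measurements that need statistical power use larger configurable
groups (typically 7–10 per arm) and state so per test.

**Gene sets.** One planted set per module whose overlap with the module
attains a configured Jaccard index (size = module size; the intersection
o solves o/(2m−o) = J), plus decoy sets drawn uniformly from the whole
gene universe. At J = 1 the planted set equals the module.

**Regulator network.** Planted pivots draw a configured fraction
(`pivot_enrichment`) of their targets from their assigned module, the rest
uniformly; decoy regulators draw all targets uniformly. ncRNA edge scores
are uniform with a configured mass above 0.5 (the paper-style cutoff is a
bare threshold, so a uniform mixture is the least-assumption score model);
TF edges carry score 1, emulating curated, unscored interactions.

One root seed drives everything; the three generators consume independent
child streams spawned from it, so each can also be called standalone and
reproduce the pipeline's output bit for bit.

**What the generator does not emulate:** platform-specific microarray
noise, probe→gene mapping, batch effects, correlated (hub-like) regulator
targeting, or any disease biology. Passing the recovery tests shows the
pipeline recovers the planted block/enrichment/pivot structure under a
well-specified factor model — not that it would resolve the messier
correlation structure of real tissue data.

## Differential expression

Welch's unequal-variance *t* with Satterthwaite degrees of freedom on log2
values, two-sided *p* from the *t* distribution. No moderated-variance
(empirical-Bayes) shrinkage: with no stated method in the motivating
design, the plain Welch test is the least-assumption choice, and the
defaults (BH *q* < 0.05, |log2FC| ≥ 1) are the conventional thresholds;
all are configurable. Degenerate genes: zero variance in both groups gives
*t* = 0, *p* = 1 when the means agree, and *p* = 0 with a `degenerate`
flag when they differ; genes flat across all samples of a contrast are
dropped before testing and logged.

BH adjustment is computed directly as the step-up quantity
q<sub>(i)</sub> = min(1, min<sub>j≥i</sub> p<sub>(j)</sub>·m/j) so the
adjusted values are exactly the textbook formula (a test cross-checks
statsmodels' `fdr_bh` at 1e−12). "q-value" throughout the package means
this BH adjustment.

The two contrasts' significant sets are merged by plain set union with
per-gene provenance (`contrast1` / `contrast2` / `both`);
|union| + |intersection| = |set1| + |set2| is property-tested.

## Coexpression modules

- **Correlation.** Pearson across samples; ≥ 3 samples and positive
  per-gene variance required (zero-variance genes are an error naming the
  gene — callers pre-filter).
- **Soft threshold.** Unsigned network a = |r|^β by default — the sign
  convention is the WGCNA default and the motivating description does not
  address sign; a signed mode ((1+r)/2)^β is kept behind a flag. β is the
  smallest integer in 1..20 whose scale-free fit reaches R² ≥ 0.8 with a
  negative slope; if none qualifies (typical for block-model data, whose
  degree distribution is bimodal rather than power-law), the β with
  maximal R² is used and a warning logged.
- **Scale-free fit.** Connectivities k<sub>i</sub> = Σ<sub>j≠i</sub>
  a<sub>ij</sub> binned into 10 equal-width bins; log10(frequency)
  regressed on log10(mean k) over usable (non-empty, positive-k) bins;
  fewer than 2 usable bins — e.g. all connectivities identical — yields an
  explicit undefined-fit flag rather than a number.
- **TOM.** The unsigned topological overlap formula above, computed by
  matrix product; a non-positive denominator (impossible for a valid
  adjacency, guarded anyway) yields 0 and a log entry. Exactness against a
  literal O(n³) triple-loop oracle at 1e−10 is an acceptance property.
- **Clustering and cutting.** Average-linkage agglomeration (scipy) of
  1 − TOM, then a *static* height cut at 0.99 of the maximum merge height
  by default, minimum module size 30, followed by iterative merging of the
  most-correlated module pair while eigengene dissimilarity 1 − cor
  < 0.25. The static cut was chosen over the hybrid dynamic-cut heuristic
  for implementability and determinism; every constant is configurable.
  Labels 1..K are assigned by decreasing size (ties by smallest member
  gene id), 0 is unassigned, and a fixed label→color table provides the
  conventional colored-module display.
- **Eigengenes.** First principal component across samples of the
  gene-standardized (mean 0, sd 1 per gene) module submatrix, unit norm,
  sign-oriented to correlate non-negatively with the module mean profile;
  variance explained is the leading eigenvalue share.
- **Module–trait.** Pearson r per (module eigengene, trait) with two-sided
  Student p on n−2 df; constant traits give a flagged undefined cell.
- **Hubs.** kME = cor(gene, module eigengene), ranked per module, ties
  broken by gene id; the top gene is the module hub.

## Enrichment

Exact hypergeometric upper tail P(X ≥ k), summed in log space (lgamma +
logsumexp) so deep tails neither under- nor overflow; exhaustive subset
enumeration for all N ≤ 12 is an acceptance property. Universe policy
defaults to the intersection of the measured genes and the collection
union ("collection" and "measured" are selectable and logged); sets are
filtered to size 5–2000 within the universe before testing (common
over-representation practice); only k ≥ 1 sets are tested, which sets the
BH denominator; significance requires p < 0.05 and q < 0.05. BH here is
the same kernel as in the differential stage (contract-tested).

## Pivot analysis

ncRNA edges are kept at score strictly > 0.5 (configurable); TF edges are
exempt because curated TF→target resources carry no interaction score.
Duplicate (regulator, target) edges collapse to the maximum score. The
"at least two pairs" gate is read as: ≥ 2 of the regulator's surviving
targets fall inside the module — the only reading consistent with a
per-pair hypergeometric test. The test universe defaults to the
module-assigned genes (labels ≥ 1), the natural frame for
regulator-vs-module comparisons; "network" and "measured" policies are
selectable. p < 0.01 is applied **unadjusted**, matching the stated rule;
an informational BH column is emitted. Pivots of ≥ 2 modules are flagged
core, and per-class (ncRNA vs TF) tallies are reported.

**Calibration regime.** The type-I measurement in the acceptance suite
uses two modules of 2,000 genes in a 4,000-gene universe with per-regulator
target counts cycling 300–700. The hypergeometric tail is discrete: in
small-module regimes the attained level of "p < 0.01" sits well below 0.01
(0.005–0.007), which would indict the test design, not the test. In the
chosen near-continuous regime the exact attained level averages ≈ 0.009,
so the measured rate is comparable to the nominal level within Monte-Carlo
error at ≥ 10,000 tested pairs.

## Workflow and determinism

A single YAML config with a schema validator (unknown keys and wrong types
are rejected before any computation) drives
simulate → diffexpr → union → coexpression → enrichment → pivot; leading
stages are skipped by supplying their input files (e.g. a `gene_list`
input replaces the differential stage). Failures abort with the stage
name. All tables are written as TSV with a fixed `%.10g` float format and
sorted, deterministic row order; the manifest records the config snapshot,
seed, package version and SHA-256 digests of every stage input and output.
Wall-clock timings are logged but kept out of the manifest so that
repeated seeded runs are byte-identical, manifest included — the property
the determinism test asserts.

## Problem sizes used in tests and the acceptance script

Module-recovery runs use 4 blocks of 50 genes plus 200 background genes,
20 samples, 10 seeds; null calibrations use 5,000 genes at 10 samples per
group; pivot calibration accumulates ≥ 10,000 tested decoy pairs; pivot
power uses 100 planted pivots across 20 seeds; the worked-example pipeline
is 2,000 genes × 24 samples. These sizes give stable Monte-Carlo error
while keeping a full run in well under a minute apiece.

## Known limitations

- The static tree cut is simpler than WGCNA's hybrid dynamic cut; heavily
  overlapping or nested modules that the dynamic cut separates may fuse or
  drop below the minimum size here.
- The scale-free criterion rarely passes on block-model data (by design of
  the model, not a defect); the fallback to maximal R² makes β
  data-dependent but deterministic.
- Welch-on-3-vs-3 defaults are underpowered, faithfully to the motivating
  design; users with n = 3 should expect few calls at q < 0.05.
- No probe summarization, batch correction, paired designs, or gene-ID
  mapping: gene identifiers are opaque strings.
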