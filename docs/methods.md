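# Methods

`troplip` re-implements, as a tested pipeline, a comparative analysis of
lipid-metabolism gene expression in placental trophoblast: case/control
single-cell RNA-seq stratified into the three trophoblast subpopulations
(villous cytotrophoblast VCT, syncytiotrophoblast SCT, extravillous
trophoblast EVT), alongside a small bulk RNA-seq hypoxia model.  This note
records the statistical models, the defaults that matter, and the design
decisions taken where the procedure admitted more than one reading.

## Expression summaries (single-cell)

CPM are computed per cell from raw counts (each cell rescaled to a total of
10⁶); cells with zero total counts are rejected rather than coerced.  For
every gene × cluster × condition stratum we report the fraction of cells
with detectable expression, the median CPM and the 95th-percentile CPM,
with zeros included.

* *Detectable expression* means raw count > 0.  No minimum-count threshold
  is applied.
* *Percentile convention*: linear interpolation between closest ranks (the
  numpy default).  On 100 cells with CPM 0…99 the 95th percentile is 94.05.
  The convention is configurable (`method`).
* *High-expressor comparison*: for a gene and cluster, the threshold is the
  95th percentile of that gene's CPM over **all** cells of the cluster with
  conditions pooled (the "global" percentile); cells strictly above it are
  compared between conditions by one-way fixed-effects ANOVA.  Pooling
  makes the selected subset invariant to condition labels; a control-only
  threshold is available via `pooled=False`.  Strata with fewer than two
  conditions or fewer than two selected cells per condition are flagged
  untestable (NaN), not raised.  ANOVA runs on untransformed CPM; a
  `log1p` option exists but is off by default.
* *Dot-plot matrix*: log2(p95 case / p95 control) per gene × cluster, NaN
  whenever either percentile is zero; the control percentile is carried as
  the dot-size driver.

## Differential expression

**Per-cell**: two-sided Mann–Whitney U on CPM within a cluster.  Exact
enumeration when both groups have ≤ 8 cells, otherwise the tie-corrected
normal approximation with continuity correction.  The reported log2FC is
log2 of the (mean CPM + 1) ratio — the pseudocount of 1 CPM guards against
zero means and is of the order of one count in a typical cell.  BH
correction is applied across genes within the cluster.

**Replicate-level (pseudobulk and bulk)**: raw counts are summed within
each (biological sample, cluster) pair — exact integer sums, empty pairs
omitted.  Each gene is then fit with a negative-binomial GLM
(log link, variance μ + φμ²) with a single condition coefficient and
median-of-ratios size factors as offsets; the Wald statistic z = β/SE gives
the two-sided normal p and doubles as the GSEA ranking metric (descending,
ties broken by gene id).  Dispersions are gene-wise method-of-moments
estimates shrunk on the log scale toward a fitted a₁/μ + a₀ trend with
weight 0.25 on the trend; genes with non-positive moment estimates fall
back to the trend.  This stage deliberately omits outlier replacement,
independent filtering and fold-change shrinkage: downstream claims rest on
directional DEG sets and rankings, not on exact coefficients, and the
lean model keeps the estimator auditable.  DEG thresholds are
|log2FC| > 0.6, BH FDR < 0.05 and (for replicate-level tests) base mean of
normalized counts > 1, all strict inequalities.

**Bulk normalization**: TMM scaling factors (reference = sample whose
upper-quartile proportion is closest to the mean; 30% trimmed from each
M tail and 5% from each A tail; precision-weighted mean of M values;
factors rescaled to geometric mean 1).  FPKM uses TMM-effective library
sizes.  The low-expression filter excludes a gene only when its median
FPKM falls in the bottom quartile of **every** experimental group —
so at least 75% of genes are always retained; the stricter "any group"
reading is available behind a flag.

## Preranked GSEA

The weighted Kolmogorov–Smirnov running sum with weight exponent 1: a set
member at rank i adds |sᵢ| / Σ|s over members|, a non-member subtracts
1/(N − n).  ES is the deviation of maximal magnitude (exact ties resolved
to the positive side).  The null is gene-label permutation (n_perm default
10,000, seeded); NES divides ES by the mean |ES| of same-sign permutations
and p gets +1 smoothing, the standard preranked convention.  Sets are
restricted to the ranked universe and skipped outside the [5, 500] size
window or when they cover the whole universe (no misses ⇒ degenerate
ES = 0).  The leading edge contains set members at or before the
running-sum maximum (positive ES) or at or after the minimum (negative).

Leading-edge overlap between sets A and B is |LE_A ∩ LE_B| / |LE_A|,
reported as "k/n (p%)" with integer rounding.  The overlap graph covers
significant (padj < 0.05) sets of one direction; both directed weights are
emitted, an edge is kept when the percentage measured from the smaller
leading edge reaches the threshold (default 25% — an artifact choice, the
source tooling does not state one), and clusters are connected components.

## Direction-aware Fisher tests

For a pathway against a direction (e.g. down-regulated), the 2×2 is
(pathway in/not in direction) × (background in/not in direction) with the
background **excluding** pathway genes; this exclusive convention is what
reproduces the published worked examples to the printed precision
(16/19 vs 7,323/24,859 → OR 12.8; 11/19 vs 4,536/20,970 → OR 4.991).
Direction membership defaults to the *sign* of log2FC (any decrease counts
as "down"), matching the scale of the published transcriptome-wide counts
(~29–35% of genes down); the thresholded DEG flag is available via
`use_significance`.  The odds ratio is the sample OR a·d/(b·c) with a
Haldane–Anscombe 0.5 correction only when a zero cell occurs — and only
for the OR, never for the exact p.  p is one-sided (greater).  BH applies
across the pathways tested in one call.  DEG-overlap tests between two
datasets use the same machinery on the co-membership 2×2 over a shared
universe (symmetric in the two sets).

## TF activity

Per TF and verdict (activated / repressed), a target is *consistent* when
its DEG label matches its regulation mode (Activation∧up or Repression∧down
for the activated verdict; mirrored for repressed).  The 2×2 crosses
consistent-significant targets against the non-target background, whose
success criterion is "significantly changed in either direction" — chosen
because target consistency is mode-dependent, so no single direction
describes the background; the source procedure does not state a
background.  Unknown-mode targets count toward the target total but are
never consistent.  One-sided (greater) Fisher p, BH across all (TF,
verdict) pairs in the call; TFs with fewer than 3 tested targets are
skipped visibly (NaN rows).  A TF with zero consistent targets gets p = 1
by construction.

## Synthetic data generator

The generator emulates the study conditions, not real tissue:

* counts are negative binomial (gamma–Poisson), variance μ + φμ², with
  φ = 0.4 for single cells and 0.05 for bulk — typical over-dispersion
  magnitudes at the two granularities;
* per-gene baselines are log-normal (log-mean 0, log-sd 1 on the per-cell
  scale, giving realistic library sizes of ~1–2 k counts over an 800-gene
  universe), modulated by per-cluster log-normal factors (sd 0.3),
  per-sample size factors (log-sd 0.15, the source of realistic
  between-replicate pseudobulk variance), and per-cell size factors
  (log-sd 0.25);
* condition effects are multiplicative 2^log2FC spikes on named gene sets
  in chosen clusters — the bundled default spikes a 19-gene
  cholesterol-biosynthesis-like set at log2FC −1 in SCT, mirroring the
  shape of the published signal; bulk spikes reuse the same machinery
  (e.g. the 5.41-fold ≈ log2FC 2.43 single-gene effect);
* regulons are (TF, target, mode) tables whose *responsive* targets are
  shifted consistently with the mode when the TF is marked active;
* spiked-set and regulon members are drawn from genes above the median
  baseline, because the gene families they stand in for are well-detected
  metabolic genes; membership blocks are disjoint, and null decoy sets are
  drawn from unspiked genes;
* one RNG per dataset, seeded from the config (streams keyed by a stable
  CRC so results are process-independent); identical config + seed gives
  byte-identical serialized outputs.

Not emulated: dropout beyond NB sparsity, doublets, batch effects, ambient
RNA, gene–gene correlation, compositional effects of normalization.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the generating model, not performance on real
tissue data.

## Numerical choices and degenerate inputs

* BH: vectorised step-up with monotonicity enforcement; NaN p-values
  propagate without counting toward m.
* IRLS for the NB GLM: closed-form 2×2 weighted solves vectorised across
  genes, 50 iterations max, tolerance 1e-8, linear predictor clipped to
  ±30; all-zero genes are excluded and reported with NaN statistics.
* All-tied Mann–Whitney inputs give p = 1 (no ordering information).
* ES ties (|max| = |min|) resolve to the positive deviation.
* Percentile thresholds use strict inequality for high-expressor selection
  ("above" the percentile), so a constant gene selects nothing.

## Problem sizes

Bundled analyses and the acceptance script run at 300–1,000 genes,
250–1,000 cells per cluster arm, and 4 replicates per bulk arm — large
enough for every recovery property to hold with margin under the
generating model while keeping full runs in seconds.  The same code paths
scale to transcriptome-sized inputs; GSEA permutation counts are the main
cost driver (10,000 permutations is the analysis-grade default; bundled
runs use 200–2,000).

## Known limitations

* The NB-Wald stage is not a DESeq2 replica; coefficients and p-values
  will differ in detail from tools with shrinkage and outlier handling.
* Wald p-values use the normal reference; with 2 + 2 replicates they are
  anti-conservative in the extreme tails (the bundled calibration checks
  run at 4 + 4).
* The permutation null for GSEA is gene-label permutation; sample-label
  permutation is out of scope.
* The TF background convention (any significant change) is one of several
  defensible choices; switching it changes absolute p-values but not the
  recovery behaviour on the bundled simulations.
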