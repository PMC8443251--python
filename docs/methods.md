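# Methods

This note documents the models, numerical conventions and design choices
behind `svzlineage`, and what its synthetic-data tests do and do not show
about real data.

## Synthetic data model

Counts follow a gamma–Poisson (negative binomial) model with a shared
dispersion α (default 0.3; `var = μ + αμ²`), the standard noise model for
UMI counts. Each cell carries latent labels: lineage stage (B quiescent,
B active, C, A dividing, A migrating), region (dorsal/ventral), cell-cycle
phase, sample barcode, and a doublet flag. A cell's expected profile is

```
μ_cg ∝ base_g · stage_g(c) · region_g(c) · phase_g(c),   Σ_g μ_cg = L_c
```

with library size `L_c` lognormal (default mean log 5000, sd 0.35 —
typical 10x depth).

Design choices that matter:

- **Program-gene baselines.** Stage, region and phase program genes draw
  baselines from the upper half of the expression distribution (folded
  normal in log space). Real marker and signature genes are detectable by
  construction — a "marker" at the 10th expression percentile could never
  be discovered or scored — so sampling program baselines from the full
  lognormal would understate the information content of real programs.
- **Constant composite regional amplitude.** Individual regional genes are
  dynamic along the lineage (constant / ramp up / ramp down / C-peak
  shapes, ±30%), but each stage's multipliers are rescaled so the
  baseline-weighted total program expression is stage-constant. The
  regional identity signal therefore persists along B→C→A while single
  genes rise and fall, which is the biological behavior the composite
  score is meant to capture.
- **Program sizes.** Regional and stage programs are 50 genes in a
  2000-gene default universe. S/G2M programs are 10 genes each: cycling
  signatures occupy roughly 0.5% of a real transcriptome, and keeping that
  proportion matters because rank-based scoring competes programs for the
  same top-rank window (see "Problem sizes" below).
- **Doublets** are Bernoulli(rate) per cell; a doublet's profile is the
  depth-weighted sum of its own and a random other-sample partner's
  expected profile, sampled once (not a mixture of two draws), and it
  carries both sample barcodes.
- **Nucleus samples** reuse the whole-cell expected profiles: dorsal cells
  are downsampled (default 50%) and re-drawn at 2× depth, reproducing
  dissections where dorsal samples had fewer cells but deeper sequencing.
- **Spots** draw a true axis coordinate t ~ Beta(a, b) per probe and are
  placed exactly on the measurement polyline at arclength t, so projection
  can be tested against a known truth.

The generator does **not** emulate ambient RNA, splicing kinetics, batch
chemistry effects, or gene–gene correlation beyond the programs. Passing
recovery tests therefore show the pipeline extracts the structure it is
designed for; they do not show robustness to contamination or to
correlated confounders absent from the model.

## Quality control and demultiplexing

Percentiles use linear interpolation on the input population with
inclusive retention bounds (UMI in [P5, P95], genes ≥ P5, mito ≤ 10%).
Filtering is population-relative: re-running on filtered output can remove
more cells, which the tests assert rather than hide. Multi-rule failures
are attributed to the first failing rule in the fixed order UMI → genes →
mito so reports are deterministic. High-UMI doublets are handled by the
upper UMI percentile rather than a separate detector.

Barcode classification thresholds each barcode's log1p counts at the
density minimum between the two tallest modes of a Gaussian KDE (fallback:
75th percentile when unimodal). Cells above threshold for exactly one
barcode are singlets; two or more, doublets; none, negative.

Reported percentages follow two conventions, both exercised by worked
examples: QC and phase fractions are **truncated** to one decimal
(4128/35025 → 11.7%; 691/992 → 69.6%), co-labeling fractions are
**rounded** to two decimals.

## Preprocessing

Normalization is `log(1 + 10⁴·x/total)` (natural log); depth-proportional
profiles normalize identically. Antibody tags use CLR:
`log1p(x_i) − mean_j log1p(x_j)`. PCA operates on gene-standardized
expression, with signs fixed so each component's largest-magnitude loading
is positive. Highly variable genes are the top 2000 by
within-bin-standardized dispersion.

Clustering builds a k-nearest-neighbor graph with shared-nearest-neighbor
(Jaccard) edge weights and runs Leiden (RB-configuration) at the five
standard resolutions; labels are relabeled 0..K−1 by decreasing size.

Cell-cycle scores are module scores: mean expression of the program minus
the mean of control genes drawn per program gene from its
mean-expression bin (25 bins, 50 controls per gene, program genes excluded
from control pools). Phase is G1 when both scores ≤ 0, otherwise the
larger score wins; the tie `s = g2m > 0` resolves to S.

## Marker discovery

The two-group test is the Wilcoxon rank-sum: exact when the combined
sample is ≤ 25 without ties, otherwise the normal approximation with tie
and continuity corrections. `log_fc` is the natural-log ratio of group
means of back-transformed (expm1) normalized expression with ε = 1e-9 —
documented explicitly because conventions differ across tools.
"Expressed" means raw count > 0. BH adjustment is per comparison.
Candidate markers require p_adj < 0.05, log_fc > 0 and pct_other ≤ 0.40.
Note the 40% rule deliberately targets *sparsely* expressed markers; on
synthetic data whose program genes are all well expressed it correctly
returns few or no candidates, and recovery there is measured on the
significant upregulated set instead.

## Regional label transfer

The reference is balanced per region after restricting to the inclusive
[P25, P75] genes-per-cell band, computed **per region** (the band could
also be computed globally; per-region is the default because it equalizes
what "mid-quality" means in samples of different depth — both are
configurable). The shared embedding is CCA: the SVD of `Zr·Zqᵀ` over
shared standardized genes, coordinates weighted by √(singular value) and
L2-normalized per cell. The weighting makes each canonical dimension
contribute in proportion to its cross-covariance; with flat weighting,
anchor distances are dominated by noise dimensions and label recovery
degrades even on perfectly separable data. A reference-PCA projection
(`method="pcaproject"`) is available as the alternative.

Anchors are mutual nearest neighbors (k = 5 per direction), scored by the
Jaccard overlap of the pair's 200-neighborhoods in the joint embedding,
min-max rescaled with anchors under 0.1 dropped. Each query cell's class
scores are a Gaussian-kernel vote over its 50 nearest anchors (bandwidth =
distance to the 50th anchor, weights scaled by anchor score, normalized to
sum 1), so scores sum to 1 and swapping class labels exactly negates the
net score. Anchor internals (neighborhood filtering, kernel, rescaling)
are this package's own definitions.

## Signature scoring

Per cell, genes are ranked by descending expression with ties broken by a
single seeded global permutation (identical profiles get identical
scores). The score is `Σ_{k≤T} R(k)` normalized by the maximum attainable
area, `T = ⌈top_frac·n_genes⌉`, `top_frac = 0.05` by default. Scores are
invariant under any strictly monotone transform of a cell's expression.
Min-max normalization maps an all-equal vector to zeros; High-Score
selection takes `d = dorsal − ventral`, HighDorsal at `d ≥ Q3`,
HighVentral at `d ≤ Q1` (linear-interpolation quartiles, boundary ties
included, zero-range input → all "neither"). Quartiles are computed over
all neurogenic-lineage cells, not within cell types. The ORA test is the
one-sided binomial tail `P(X ≥ k)`, `X ~ Bin(|query|, |set|/|background|)`
with BH across sets (hypergeometric available).

## Gene regulatory networks

Each target (unit-variance scaled) is regressed on all candidate
regulators except itself by a random forest with `mtry = ⌊√p⌋`; link
importance is summed impurity reduction. Marker networks keep the top 300
links touching a marker — restriction first, truncation second — with
boundary ties broken by (regulator, target) lexicographic order.
Gene-centric networks take the top-20 partners of the focal gene, then
each partner's top-20, with all links among included nodes. Metrics use
the undirected simple graph; the clustering coefficient is the mean local
coefficient with degree-<2 nodes contributing 0 (global transitivity is
provided as `global_transitivity` for comparison).

## Spatial quantification

The axis coordinate is the normalized arclength of the nearest point on
the measurement polyline (orthogonal projection per segment, clamped at
vertices; shapely's linear referencing), invariant to rigid transforms of
spots and axis together. The dorsal domain is the most dorsal third,
boundary inclusive (`t ≥ 2/3`, arclength metric). The two-group t test is
pooled-variance by default (Welch optional); zero pooled variance with
equal means returns p = 1.

## Problem sizes and numerical conventions

Default simulations use 1000 cells × 2000 genes, which keeps every test
fast on one CPU. One property is evaluated at 8000 genes: the constancy of
the composite regional score along the lineage. Rank-based set scoring
competes all programs for the same top-5% window, and in a small universe
the cycling programs occupy a visible share of that window, depressing
regional scores specifically in the cycling C compartment; at
transcriptome-like scale the effect is negligible, and that is the regime
in which the constancy claim lives. Tolerances: formula-oracle agreements
at 1e-12, eigenvector/orthonormality at 1e-8, projection oracles at 1e-6,
recovery-curve oracle at 1e-9. All randomness flows from one seed through
`derive_seed(seed, label)` (sha256, reduced mod 2³¹).

## Known limitations

- Regularized NB normalization and anchor-based batch integration are out
  of scope; normalization is log-based and batch handling is per-batch
  centering.
- The barcode classifier is a KDE split, not the original quantile-sweep
  algorithm; it assumes clearly bimodal barcode distributions.
- Phase calling on NB counts with 10-gene programs is noisy for G1 cells
  whose scores hover near 0 (the G1 rule is a hard threshold at 0); the
  ≥90% recovery contract is met at additive effect +2 on matched data.
- GRN importances are predictive, not causal; directed edges are kept for
  display only and ignored by all metrics.
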