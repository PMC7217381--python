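# Methods

This note documents the models, conventions and numerical choices
behind `mkbias`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Synthetic cohort model

The generator produces negative-binomial UMI counts for a two-group
(case = myelofibrosis-like, control = healthy-donor-like) cohort:

- **Baseline abundances.** Per-gene means are log-normal (σ = 1.2),
  scaled so a typical cell has ≈ 3,000 UMIs. Mitochondrial genes (an
  explicit index set, named `MT-*`) are pinned to 5% of the library.
  Lineage-program genes share the median baseline abundance: markers
  are moderately expressed when off and dominant when on, which is the
  regime in which rank-based signature scores behave like their
  real-data counterparts.
- **Library sizes.** Per-cell log-normal factors (σ = 0.3 in log
  space).
- **Counts.** NB with gene-level dispersion φ = 0.2 (Var = μ + φμ²), a
  mid-range value for droplet UMI data; all draws come from a single
  `numpy` generator seeded once, so identical parameters and seed give
  byte-identical output.
- **Batch effects.** Multiplicative per-donor per-gene log-normal
  factors (σ = 0.15), i.e. exactly the location/scale structure the
  empirical-Bayes adjustment is designed to remove.
- **Lineage structure.** Each cell carries a latent pseudotime
  t ∈ [0, 1] and a branch label drawn from per-group proportions
  (megakaryocyte branch 4.98% in cases vs 0.44% in controls by
  default; erythroid/myeloid 25%, lymphoid 5%/15%, remainder
  uncommitted). A 20-gene HSC root program decays, and the branch's
  20-gene program rises, linearly in t with saturation at t = 0.6:
  committed cells (t > 0.6) express their program fully (2^4 = 16-fold),
  matching the discrete-cluster structure of real progenitor data where
  canonical markers (e.g. PF4 for MkPs) are decisively on. Setting the
  saturation to 1.0 yields a purely linear activation, used for
  pseudotime-recovery experiments.
- **Genotype effects.** Case cells are mutant with probability 0.8;
  designated megakaryocyte-program genes are up-regulated 2^1.5-fold in
  mutant cells. A separate plate-style dataset fixes the group sizes at
  678 / 388 / 1,668 (WT-HD / WT-patient / mutant) and plants the
  G6B-like marker's expressing frequencies at 0.147 / 0.229 / 0.32 with
  a 2-fold level effect in mutants.
- **Artifacts for QC.** 2% pDC-like contaminant cells (own 20-gene
  program) and 2% low-quality cells rescaled to 200–600 expected UMIs
  with a 10× mitochondrial boost, so the QC filter has genuine true
  positives.

What the generator does **not** emulate: ambient RNA, doublets,
cell-cycle structure, realistic gene–gene correlation beyond the
planted programs, zero-inflation beyond NB sampling, or the real data's
scale (33k genes, 135k cells). Recovery results on synthetic cohorts
therefore demonstrate correctness of the statistical machinery under
the model's assumptions, not robustness to every real-data artifact.

## Preprocessing conventions

- **QC bounds** are typed exactly: UMI strictly > 1,000, genes
  strictly > 500, mito fraction strictly < 0.15, per-donor maxima
  inclusive (≤). When per-donor caps are not supplied they default to
  the donor's 99.5th percentile; the resolved caps are recorded in the
  QC report, and re-filtering with those recorded caps is a no-op
  (idempotence holds for explicit thresholds; re-deriving quantile caps
  from an already-filtered matrix would tighten them).
- **Normalization** is counts-per-10,000 then log2(1 + x). log2 is used
  throughout for internal consistency (the plate-based protocol is
  log2; the log base is configurable). "Expressing" always means raw
  count > 0.
- **HVG statistics** are computed on library-size-scaled *pre-log*
  values, where the CV²-vs-mean decomposition of technical noise
  applies. The trend CV²(μ) = a₁/μ + α₀ is fitted by a gamma GLM with
  identity link via IRLS (weights 1/fitted², relative deviance change
  < 1e-8, ≤ 100 iterations; degenerate designs fall back to least
  squares). The **dispersion score** is observed − fitted CV²
  (a difference, not a ratio): it is monotone in the excess variance at
  fixed mean and keeps the 0.05 cutoff on the same scale as CV² itself.
- **Flagged-gene removal** matches name prefixes `MT-`, `RPS`, `RPL`,
  `HSP` (or an explicit list).
- **Donor-effect adjustment** is the standard parametric empirical-
  Bayes location/scale scheme: standardize per gene against the
  batch-size-weighted grand mean and pooled variance, estimate
  per-batch location (γ) and scale (δ²) effects, shrink them toward
  normal / inverse-gamma priors by the usual fixed-point iteration
  (convergence 1e-4, matching the reference implementations, including
  their population-variance convention for the γ hyperprior), adjust
  and back-transform. Two consequences worth knowing: (i) the pooled
  per-gene mean is preserved only approximately — shrinkage leaves a
  residual of order the prior variance, identical in the reference
  implementations; (ii) a batch effect carried by a small minority of
  genes is deliberately under-corrected, because the prior is dominated
  by null genes. Per-donor per-gene effects — the realistic regime —
  are removed to ≥ 95% of between-batch variance in the tests.

## Graph clustering

PCA is computed by full SVD on the gene-centered matrix with a
deterministic sign convention (largest-magnitude loading positive).
The elbow is the variance point maximizing perpendicular distance to
the line joining the first and last points; the pipeline default
overrides it to 20 PCs.

The SNN graph uses neighbor lists that include the cell itself plus its
k nearest neighbors (Euclidean metric, distance ties broken by
ascending cell index via stable sort). An edge (i, j) exists when
either cell is in the other's list; its weight is |L(i) ∩ L(j)|/(k+1),
so weights lie in [0, 1] and duplicated points get weight 1. k defaults
to 30, mirroring the embedding neighborhood size. Louvain runs on the
weighted graph through igraph with an explicitly seeded RNG; labels are
canonicalized by first appearance. Cluster merging is only ever an
explicit, logged mapping supplied by configuration. 2-D layouts (UMAP
with 30 neighbors / cosine metric; seeded spring layout for the
force-directed view) are visualization contracts only — no statistic is
computed from them.

## Signature scores and gating

Mean-expression scores are plain means of log-normalized expression
over the set's genes present in the matrix (missing identifiers are
reported, never silently dropped). Lineage assignment uses per-lineage
thresholds defaulting to the 90th percentile of control-group scores —
a scale-free stand-in for a manual cutoff — and labels a cell
uncommitted when zero or ≥ 2 lineages exceed. The AUC score ranks all
genes per cell by decreasing expression (ties broken by one seeded
shuffle then stable sort), computes the area under the recovery curve
of the set within the top ⌈5% × n_genes⌉ ranks and normalizes by the
maximal area; being rank-based it is invariant to monotone transforms,
so raw or normalized input is immaterial. The MkP gate is strict:
score > 0.4. Contaminant clusters are those whose mean pDC-signature
score strictly exceeds the rule's threshold (default: cohort mean +
3 SD of the per-cell score).

## Differential expression

The combined test couples a Wilcoxon rank-sum test on levels (all
cells, zeros included; exact enumeration when both groups have n ≤ 8
without ties, otherwise the tie- and continuity-corrected normal
approximation) with a Fisher's exact test on expressing frequencies,
via Fisher's method on 4 df. The two component tests are computed on
the same cells and are **positively dependent**, so the combination is
not exactly calibrated; rather than correct it we quantify it: the
empirical type-I error at α = 0.05, measured on ~3,000 complete-null
genes per run (random splits of same-group synthetic cells at the
generator's defaults), is ≈ 0.066 — mildly anti-conservative, within
the 0.02–0.07 band the tests assert. The level rises with group size
(Fisher's discreteness conservatism vanishes) and would exceed 0.07 at
plate-scale groups; marker calls additionally pass effect-size and
frequency filters, which is why the slight miscalibration is tolerable
in practice. log2FC is the difference of group means of log2(1 + x).
BH adjustment is applied per cluster-vs-rest comparison (the smallest
defensible family; a global family would only change q by a constant
factor log-wise). Zero p-values are floored at 1e-300 before logs.

## Composition

Signature proportions are summarized per donor, and the case/control
comparison is a Wilcoxon rank-sum over donors — the donor, not the
cell, is the independent unit. The fold is reported at full precision
with a rounded integer convenience field (4.98/0.44 → "11-fold").
Down-sampling is uniform without replacement within the group, seeded.
The Yates chi-square caps the correction at |O − E| − 0.5 ≥ 0.

## Trajectory

Diffusion maps use a Gaussian kernel on the kNN graph with adaptive
bandwidth (distance to the ⌈k/2⌉-th neighbor), symmetrization, density
normalization, and a symmetric eigensolve with a fixed ARPACK start
vector (determinism). Components are scaled by λ/(1 − λ) — the
accumulated-transition kernel — so slow trajectory components dominate
fast noise components, and pseudotime is the Euclidean distance from
the root in that space, rescaled to [0, 1]; cells outside the root's
connected component get infinite pseudotime. The root defaults to the
cell maximizing the HSC signature score. This
diffusion-distance-from-root construction replaces a full abstracted-
graph partition: the quantity used downstream is only the ordering of
cells along an explicitly supplied cluster path. Path profiles are
running means (window `n_avg` = 5,000, truncated to the path length)
over cells ordered by pseudotime; trend genes are ranked by |Spearman
rho| against pseudotime with constant genes assigned rho = 0.

## Enrichment

The preranked metric is sign(log2FC) × (−log10 combined p), ties broken
by |log2FC| then gene id. ES is the extreme of the weighted KS running
sum (hit increments ∝ |metric|¹, normalized; uniform miss decrements).
The null permutes gene labels (the only option for preranked input);
NES divides ES by the mean |null ES| of matching sign, nominal p is the
same-sign tail fraction, and FDR q follows the standard sign-stratified
pooled-null procedure, capped at 1. Set-size bounds default to 15–500.
On null rankings ~2% of random sets reach q < 0.25 in the calibration
tests.

## Problem sizes and runtimes

The test and benchmark cohorts use 600–1,000 genes and 1,000–4,000
cells (2–4 donors per group, 120–575 cells each), fold-recovery runs
use 21 donors × 2,000 cells with a 50-gene panel, and the determinism
check runs the full pipeline twice on ~1,000 genes × ~4,000 cells.
These sizes were chosen so every planted effect is estimated with
comfortable margin while a full suite run stays in the minutes range.

## Known limitations

- The Louvain permutation-invariance property is exact only up to the
  greedy optimizer's tie handling; it is asserted on well-separated
  structures.
- The combined DE test's calibration drifts anti-conservative with
  very large groups (see above).
- The AUC gate's absolute scale depends on the ratio of set size to
  the top-rank cutoff; with small gene panels the cutoff must be
  interpreted relative to that ratio.
- The empirical-Bayes batch adjustment assumes batch effects shared
  (in distribution) across many genes; isolated single-gene batch
  artifacts are shrunk, not removed.
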