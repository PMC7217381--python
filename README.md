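# mkbias

Single-cell analysis of **megakaryocyte-biased hematopoiesis in
myelofibrosis**, packaged as a tested, reusable pipeline.

Myelofibrosis is a myeloproliferative neoplasm in which mutant
(JAK2V617F / mutCALR) hematopoietic stem and progenitor cells (HSPCs)
produce a dramatic excess of megakaryocytes that drive bone-marrow
fibrosis. Droplet scRNA-seq of CD34+ lin− HSPCs shows a strongly
expanded megakaryocyte-progenitor (MkP) compartment in patients, and
plate-based genotyped transcriptomes show that megakaryocyte surface
genes — above all *MPIG6B* (G6B) — are over-expressed specifically in
mutant-clone cells, making G6B a candidate immunotherapy target. This
package implements the full analysis chain behind those observations,
plus a synthetic-cohort generator that plants every effect the pipeline
is supposed to detect, so the whole chain is testable without any
external data.

## What the pipeline computes

Given a 10x-style count triplet (`matrix.mtx`, `features.tsv`,
`barcodes.tsv`) with per-cell donor/group/genotype metadata:

1. **QC** — keep cells with UMI > 1,000 (and ≤ a per-donor cap), genes
   detected > 500, mitochondrial fraction < 15%; keep genes expressed in
   ≥ 10 cells.
2. **Normalization** — counts per 10,000 per cell, log2(1 + x).
3. **Highly variable genes** — per-gene squared coefficient of
   variation CV² is fitted against the mean with a gamma GLM (identity
   link), CV²(μ) = a₁/μ + α₀; genes with mean > 0.05 and dispersion
   score (observed − fitted CV²) > 0.05 are selected, then ribosomal /
   mitochondrial / heat-shock genes are removed.
4. **Donor-effect removal** — parametric empirical-Bayes location/scale
   adjustment (ComBat-style) over donors.
5. **Clustering** — PCA (elbow-selected, default 20 PCs), shared-
   nearest-neighbor weighted kNN graph (weight = normalized shared
   neighbor count), seeded Louvain modularity optimization; a
   plasmacytoid-dendritic-cell-like contaminant cluster is flagged by
   signature score and removed, then clustering is re-run.
6. **Lineage signatures** — per-cell mean log-normalized expression of
   erythroid / megakaryocyte / myeloid / lymphoid gene sets; a cell is
   assigned the unique lineage whose score exceeds its threshold, else
   "uncommitted" (gray) — including when >1 lineage exceeds.
7. **Composition** — per-cluster donor-type composition with
   down-sampling of the larger group, and per-donor signature
   proportions with the case/control fold (the study's headline
   4.98% vs 0.44% ≈ 11-fold).
8. **MkP gating** — AUCell-style area-under-recovery-curve score of the
   megakaryocyte signature within each cell's top 5% expression ranks;
   cells with score > 0.4 are gated as MkP.
9. **Differential expression** — per gene, a two-sided Wilcoxon
   rank-sum test on log-normalized levels **and** a Fisher's exact test
   on expressing-cell frequencies, combined by Fisher's method
   (−2Σln p ~ χ² with 2k df), BH-adjusted; markers require |log2FC| ≥
   0.5, q < 0.05, expressing fraction > 0.3, top 50 per cluster.
   The same combined test compares genotype groups
   (WT healthy-donor / WT patient / mutant) for single genes, and a
   Yates-corrected chi-square compares mutant/WT cluster proportions.
10. **Trajectory** — diffusion maps on the PC embedding, pseudotime as
    diffusion distance from an HSC-rooted cell, running-average
    expression profiles along a designated path (window `n_avg`, default
    5,000), and trend-gene (transcription-factor) ranking by Spearman
    correlation with pseudotime.
11. **Enrichment** — preranked GSEA (weighted running-sum ES,
    gene-label permutation null, NES, sign-stratified FDR q; pathways
    with q < 0.25 reported).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data:

```bash
python analysis/01_simulate_cohort.py --seed 1   # writes results/data/
python analysis/02_run_pipeline.py   --seed 1    # full pipeline
python analysis/03_genotype_targets.py           # G6B-like genotype tests
python analysis/04_recovery_benchmarks.py --seed 1
```

`03_genotype_targets.py` prints, for the simulated plate dataset with
the study's group sizes (678 WT-HD / 388 WT-patient / 1,668 mutant) and
planted marker frequencies (14.7% / 22.9% / 32%):

```
marker gene G00000: pairwise genotype comparisons
   group_a    group_b  frac_expressing_a  frac_expressing_b  p_fisher  p_wilcoxon  p_combined
     WT-HD WT-patient              0.165              0.281  1.03e-05    2.17e-05    5.16e-09
     WT-HD     mutant              0.165              0.327  4.65e-16    3.56e-20    1.34e-33
WT-patient     mutant              0.281              0.327    0.0901    0.000146    0.000161

reconstructed frequency test (32% of 1668 vs 14.7% of 678): Fisher p = 9.33e-19
reconstructed surface-fraction test (28.8+/-5.5 n=11 vs 2.4+/-1.0 n=8): Welch t = 4.72, p = 0.000684
```

i.e. the G6B-like marker is detected in a significantly larger fraction
of mutant cells than wild-type cells (frequency and level effects both
contribute to the combined p), and the reconstructed in-study statistics
are far below their significance thresholds. `04_recovery_benchmarks.py`
reports, among others, clustering ARI 1.0 on an 8-block planted
structure, marker recall 1.0 with zero sub-threshold genes passing, MkP
gate recall 1.0 at AUC > 0.4, the planted 11.3-fold megakaryocyte
fraction recovered within ~2%, pseudotime Spearman ≈ 0.99, and a
combined-test type-I error of ≈ 0.066 at α = 0.05.

## Layout

```
src/mkbias/       library: simulate, io, preprocess, cluster, signatures,
                  diffex, composition, trajectory, enrichment, config,
                  pipeline, cli, validation
analysis/         numbered narrative drivers
tests/            pytest suite (unit, property and acceptance tests)
scripts/          acceptance script
docs/methods.md   model and methods notes
```

A thin CLI is installed as `mkbias` with subcommands mirroring the
stages (`simulate`, `qc`, `preprocess`, `cluster`, `score`, `markers`,
`genotype-test`, `composition`, `trajectory`, `gsea`, `run-all`).
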