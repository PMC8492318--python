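# Methods

This note documents the models, parameter conventions, and numerical
choices behind `isletstrat`, in the spirit of a package methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The stratification model

Each α cell is classified by the joint detection of ARX and MAFB, each β
cell by MAFA and MAFB. Detection of a TF in a cell is a binarized call on
the normalized scale

```
x = ln(UMI / cell_total × size_factor + 1),   size_factor = 10,000
```

with a cell counted *detected* iff `x > 0.5`. Values exactly at the
threshold are assigned to the low state — a conservative call, since the
bound is configurable and the choice only matters for the measure-zero
boundary. The two indicator bits map each cell to one of four groups,
`None / A-only / B-only / Both`, which partition the target cells;
fractions are reported pooled and per donor and sum to one by
construction. An alternative `detection="nonzero"` mode calls a TF
detected on any transcript, for sensitivity analyses of the threshold
choice.

At a typical droplet library (~1000–5000 UMI) a single TF count already
normalizes to ≈ 1.1–2.4, so the 0.5 threshold effectively asks for at
least one molecule; the binarization is a detection call, not an
abundance estimate, and the package makes no claim about protein levels
in cells with undetected transcripts.

## 2. Quality control

Filters follow droplet-islet practice and are all exposed in `QCParams`:

| parameter | default | note |
| --- | --- | --- |
| `min_genes` / `max_genes` | 200 / 4000 | inclusive bounds on detected genes |
| `max_mito_fraction` | 0.10 | strict (`<`), `MT-` symbol prefix, regex configurable |
| `min_cells_per_gene` | 3 | applied to retained cells |
| `ins_doublet_threshold` / `gcg_doublet_threshold` | 6.5 / 5.0 | normalized-log units |
| `positive_level` | 4.0 | cross-lineage "positive" call |
| `ambient_umi_cutoff` | 100 | barcodes at/below define the ambient pool |
| `ambient_prominence` | 0.001 | min share of pooled ambient counts |

**Hormone doublets.** Two rules, each recorded per dropped cell. The
coexpression rule removes cells with INS > 6.5 *and* GCG > 5.0. The
cross-lineage rule removes cells in which INS or GCG is positive
(> `positive_level`) together with a positive marker of a *different*
lineage; a hormone's own lineage markers are excluded (an α cell positive
for GCG, TM4SF4, and IRX2 is a healthy α cell, not a doublet), and the
INS+GCG pairing itself is governed solely by the coexpression rule so the
two rules cannot shadow each other. `positive_level` defaults to 4.0,
comfortably above the normalized level that ambient contamination
produces in foreign cells (~3 at 2% contamination) and below genuine
marker expression (~5–8).

**Ambient correction.** Barcodes with total UMI ≤ 100 form the ambient
pool; genes holding ≥ 0.1% of the pooled ambient counts are the ambient
gene list. The expected ambient count of gene *g* in a droplet is
`profile_g × mean(empty-droplet totals)` — a per-droplet constant, because
cell-free transcripts load droplets independently of how much cellular
RNA a droplet also captured. The expectation is rounded half-up and
subtracted from every cell's raw count, clipped at zero; non-ambient
genes are untouched, so corrected counts never exceed raw counts. Scaling
the subtraction with each cell's total was considered and rejected: with
a hormone-dominated ambient pool (GCG alone is ~10% of ambient content)
a proportional rule would remove ~10% of a true α cell's GCG, distorting
the endocrine signal the pipeline is meant to preserve. On simulated data
the per-droplet rule removes ≥ 50% of ambient hormone counts in
non-endocrine cells while changing true endocrine hormone counts by < 3%
(asserted in the test suite at 5% contamination).

The pipeline applies ambient correction before cell filtering by default
(it needs the raw barcode matrix including empties); the stage can be
disabled (`run_ambient=False`), and the stratification can be run on
either ordering since all stages are plain functions.

## 3. Clustering and annotation

Pipeline: top-variable-gene selection (dispersion = variance/mean of the
normalized values, z-scored within 20 mean-expression bins; count
default 2000, capped at the gene panel) → per-gene scaling to zero mean
and unit variance after linear regression-out of the mitochondrial
fraction, clipped at ±10, zero-variance genes dropped with a log message
→ PCA (20 components, seeded) → symmetric kNN connectivity graph
(k = 20) → Louvain multilevel community detection at resolution 0.6 with
a seeded RNG, so identical seeds give identical partitions.

Annotation z-scores each marker gene's cluster means across clusters
(sample SD) and labels a cluster with the cell type whose markers have
the highest mean z. Ties resolve toward the type with more markers
detected in the cluster, then lexicographically, with a logged warning.
Rare γ and ε cells, which co-cluster with δ cells at realistic
abundances, are relabeled by an explicit rule — PPY (γ) or GHRL (ε)
normalized expression > 0.5 within the δ cluster — replacing interactive
lasso selection with a reproducible criterion on the same scale as the TF
binarization. The shipped marker table is a standard islet reconstruction
(GCG/TM4SF4/IRX2 → α, INS/IAPP/NKX6-1 → β, SST/HHEX → δ, PPY → γ,
GHRL → ε, PRSS1/CPA1 → acinar, KRT19/SPP1 → ductal, PECAM1/PLVAP →
endothelial, COL1A1/PDGFRB → stellate, PTPRC/SDS → immune) and is
user-overridable everywhere it is consumed.

## 4. Group statistics

All group comparisons route through `isletstrat.stats` — one
implementation for the transcript panels, the differential-expression
tests, and the electrophysiology features.

* **Mann-Whitney U**, two-sided. Exact null when both samples have ≤ 8
  observations and no ties; otherwise the normal approximation with tie
  correction and continuity correction. Fully tied inputs are degenerate:
  `U = nm/2, p = 1`.
* **BH adjustment** by the standard step-up; adjusted p ≥ raw p always.
  The family spans all genes × all comparisons jointly by default
  (`bh_family="per_comparison"` available); the comparison scheme is
  *Both vs each other group* by default with an all-pairs option.
* **Dot-plot statistics**: percent detected = fraction of the group's
  cells with any transcript (raw count > 0 — standard dot-plot semantics,
  deliberately more permissive than the 0.5 detection call); z-scores
  standardize the four group means per gene with the sample (n−1) SD;
  zero-variance genes get z = 0, fully undetected genes are additionally
  flagged.
* **Underpowered groups** (< 3 cells in the electrophysiology module) are
  reported but not tested, and excluded from the BH family.

Bulk differential expression uses `log2FC = log2((TPM_a+1)/(TPM_b+1))`
with a z-score of each gene's log2FC against the across-gene
distribution — the single-replicate normal approximation, documented as
approximate — BH adjustment, and the significance rule
`|log2FC| ≥ 1 ∧ p_adj < 0.05`. Single-cell DE pairs the same fold-change
rule (on mean UMI, pseudocount 1) with the Mann-Whitney test across
cells. The fold-change concordance statistic correlates the two log2FC
vectors on jointly significant genes and counts opposite-sign genes. For
the noise-free exactness check the correlation is computed with
pseudocount 0 on jointly detected genes, where bulk TPM and pseudobulk
mean differ by a per-sample constant and r = 1 exactly; with pseudocount
1 the two scales distort differently and exactness is lost, which is why
`fc_pseudocount` is a separate knob.

## 5. The synthetic-data generator

`generate_dataset` emulates a dispersed human islet preparation:

* **Census** — ten cell types at proportions typical of isolated islets
  (α 54%, β 24%, stellate 7.7%, ductal 4.7%, acinar 3.3%, δ 2.5%,
  endothelial 2.2%, immune 0.8%, γ 0.6%, ε 0.2%), five donors.
* **Counts** — negative binomial with variance `μ + φμ²` (φ = 0.25),
  gene-level means per type: hormone 200, other own-type markers 30,
  program genes 5 in endocrine types, background lognormal around 1.2,
  all multiplied by per-donor lognormal batch factors (σ = 0.1) and a
  per-cell lognormal library factor (σ = 0.3). ARX is also on in γ/ε
  cells and MAFB moderately in immune cells, mirroring their known
  distributions.
* **TF states** — each α/β cell draws a group from the planted 4-vector
  (defaults: α 0.10/0.04/0.48/0.38, β 0.22/0.04/0.52/0.22). An *on* TF
  has mean 15 expected counts so the on/off separation is decisive
  (off-state dropout < 0.5% across the library distribution); an *off* TF
  has mean 0.002, small but nonzero so true absence and dropout remain
  distinguishable. A larger off-state ε (e.g. 0.02) makes a single stray
  transcript cross the detection threshold in ~2% of off cells and
  shifts the recovered B-only/Both fractions by about one binomial SD at
  n = 5000 — a systematic classification bias, which is why the default
  is an order of magnitude lower and the parameter is exposed.
* **Program coupling** — *Both*-group cells scale their functional
  program genes (20 genes spanning identity, glucose metabolism, ion
  flux, trafficking, exocytosis) by `program_effect` (default 2;
  `program_effect=1` is the null used for error-rate checks).
* **Mitochondrial load** — per-cell fraction from Beta(2, 38)
  (mean 5%), allocated across eight MT- genes.
* **Ambient RNA** — the ambient profile is the library-size-weighted mean
  of all true cells' gene proportions; each droplet swaps a
  Binomial(count, 2%) portion of its molecules for multinomial draws from
  that profile. Empty droplets (default 500) carry only ambient counts
  with totals uniform on 10–80.
* **Doublets** — 5% of cell barcodes are sums of two independently
  generated cells with types drawn from the census, so a doublet's total
  UMI always dominates either parent.
* **Planted QC failures** — `low_quality_rate` cells get a 5× smaller
  library and +0.2 mitochondrial fraction, to exercise the filter ledger.

One RNG stream per dataset, seeded from the config; identical configs
give byte-identical output. The matched bulk generator sums singlet
counts of a type and rescales to counts-per-million (the TPM analogue for
3′ UMI data, where no length term applies). The electrophysiology
generator draws Gaussian features around per-feature baselines with a
shared noise SD and additive group shifts (cell size is unshifted by
default — the published null); the intensity generator draws two-channel
Gaussian mixtures around low/high modes with planted quadrant fractions,
tolerating rounded percentage vectors that sum to 99%.

**What the generator does not model:** transcriptome-wide co-expression
structure beyond the TF-program coupling, spliced/unspliced kinetics,
batch effects needing integration, empirical TF on-state distributions
(unknown; the defaults are free parameters), or Patch-Seq full-length
chemistry. Passing tests therefore demonstrate the pipeline's logic and
statistics under a controlled overdispersed-count model, not performance
on any particular real preparation.

## 6. Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to keep binomial
error bars meaningful: 5000 cells per type for fraction recovery (3
binomial SDs ≈ 0.8–2 percentage points), 2000-cell pipeline runs for
ledger accounting, 50 replicates × 400 cells for the null error rate,
2000 cells (≈500/group) for power, 100 replicates × 40 cells/group for
electrophysiology rates, and ~1500-cell preparations for concordance.
All randomness flows from explicit seeds (`--seed` in the CLI and
acceptance script, spawned per block); reruns are byte-identical,
including `summary.json`.

## 7. Known limitations

* The z-score bulk DE p-value is a scale approximation, not a
  replicate-based test; with one bulk sample per cell type nothing
  stronger is identifiable.
* The single-cell DE statistic behind the concordance figure is a
  documented choice (Mann-Whitney on normalized values); rank tests on
  droplet counts are conservative under heavy ties.
* Louvain partitions depend on graph construction; only seed-level
  determinism is guaranteed, not stability across igraph versions.
* The cross-lineage doublet rule cannot flag same-lineage doublets
  (α×α, β×β), which is inherent to marker-based rules.
* Ambient correction subtracts an expectation; it does not model
  per-cell contamination variance.
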