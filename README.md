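# isletstrat

Combinatorial transcription-factor (TF) stratification of pancreatic islet
α and β cells from droplet single-cell RNA-seq.

## The problem

Islet-enriched TFs such as ARX, MAFA, and MAFB control α- and β-cell
identity and hormone secretion, yet in single-cell data each of these TFs
shows a clearly bimodal detection pattern: a subpopulation of cells carries
no detectable transcript at all. Classifying every α cell by the joint
detection of **ARX/MAFB** (and every β cell by **MAFA/MAFB**) yields four
combinatorial groups — *None*, *A-only*, *B-only*, *Both* — and the
dual-positive group shows elevated expression of glucose-sensing,
ion-channel, and exocytosis genes, plus enhanced electrophysiological
activity in Patch-Seq data. `isletstrat` implements this stratification as
a reproducible pipeline for computational biologists who want to apply or
probe it: bespoke droplet QC, the four-way classifier with its subgroup
statistics, bulk/single-cell concordance metrics, an electrophysiology
group comparison, and a ground-truth synthetic-data generator so every
stage is testable without any external download.

## The method in brief

* **Detection call.** A TF is *detected* in a cell iff its normalized
  expression `ln(UMI / cell_total × 10,000 + 1)` exceeds **0.5** (values at
  the threshold count as low). The pair of indicator bits maps each target
  cell to one of the four groups; fractions are reported pooled and per
  donor.
* **QC.** Cells with 200–4000 detected genes (inclusive) and <10%
  mitochondrial counts are retained; genes need ≥3 expressing cells.
  Hormone-coexpressing doublets are dropped when normalized INS > 6.5 **and**
  GCG > 5.0, or when INS/GCG is positive together with a marker of a
  different lineage. Ambient transcripts are estimated from empty droplets
  (total UMI ≤ 100) and their expected per-droplet contribution is
  subtracted from every cell, clipped at zero.
* **Clustering/annotation.** Top variable genes → scaling with
  mitochondrial-fraction regression → PCA (20 PCs) → kNN graph → Louvain
  (resolution 0.6) → marker-argmax annotation; rare PPY+/GHRL+ cells are
  relabeled out of the δ cluster by an explicit threshold rule.
* **Statistics.** Group comparisons use two-sided Mann-Whitney U (exact
  null for ≤8 per side without ties, tie-corrected normal approximation
  otherwise) with Benjamini-Hochberg adjustment across the full
  gene × comparison family. Dot-plot summaries report percent detected,
  group mean expression, and the cross-group z-score (sample SD). Bulk vs
  single-cell differential expression uses the `|log2FC| ≥ 1` + z-score-p +
  BH-0.05 rule with detection filters `log2(TPM) > 1` (bulk) and
  `mean UMI > 1` (single cell).

## Worked example

Run the full pipeline on a seeded synthetic islet preparation (~2500 cells
across ten cell types, five donors, 5% doublets, 2% ambient
contamination, 500 empty droplets):

```python
import isletstrat as ist

cfg = ist.PipelineConfig(
    simulate=ist.SimConfig(seed=1, n_cells_per_type=ist.simulate.default_census(2500)),
    seed=1,
    outdir="run1",
)
summary = ist.run_pipeline(cfg)
```

With seed 1 this prints (via the summary dict):

```
retained: 2292 of 3124
clusters: 8
alpha {'None': 0.077, 'A-only': 0.036, 'B-only': 0.428, 'Both': 0.459}
beta  {'None': 0.168, 'A-only': 0.03,  'B-only': 0.541, 'Both': 0.26}
fc_correlation: 0.942
ephys significant: ['early_ca_current_pA_pF', 'early_exocytosis_fF_pF',
                    'late_ca_conductance_nS_pF', 'late_ca_current_pA_pF']
```

Reading the numbers: of 3124 input barcodes, 500 empties, QC failures, and
hormone doublets are removed (the run directory's `drop_ledger.tsv`
accounts for every barcode exactly once). The four-way α fractions recover
the planted generator state (10/4/48/38%) shifted slightly toward *Both*
because ambient ARX/MAFB transcripts leak into truly negative cells —
rerun with `ambient_fraction=0.0` and the planted fractions come back
within binomial noise. The bulk-vs-single-cell fold-change correlation of
0.94 on jointly significant genes shows the two modalities rank α/β
differences concordantly, and the electrophysiology comparison flags
exactly the four features the simulation shifted in the dual-positive
group — cell size stays null.

The same stages are available from the shell:

```bash
isletstrat simulate --seed 1 --out sim/
isletstrat run-all --config pipeline.json
```

## Layout

| module | contents |
| --- | --- |
| `isletstrat.simulate` | `SimConfig`, `generate_dataset`, matched bulk, ephys, intensity generators |
| `isletstrat.qc` | filters, normalization, hormone-doublet + ambient rules |
| `isletstrat.cluster` | HVG/PCA/kNN/Louvain, marker annotation, rare-cell rules |
| `isletstrat.stratify` | four-way classifier, dot-plot stats, group tests, intensity analogue |
| `isletstrat.concordance` | pseudobulk, detection-filtered correlation, paired DE |
| `isletstrat.ephys` | Patch-Seq-style feature comparisons |
| `isletstrat.pipeline` / `isletstrat.cli` | orchestration, config, drop ledger, CLI |

See `docs/methods.md` for the model, parameter defaults, and numerical
conventions.
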