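"""Cell/gene quality-control filters, normalization, hormone-doublet
removal, and ambient-transcript correction.

The filters follow common droplet scRNA-seq practice for islet
preparations: retain cells with 200-4000 detected genes (inclusive) and
less than 10% mitochondrial content; keep genes expressed in at least 3
retained cells; normalize each cell to a fixed size factor (10,000
molecules) and log-transform; drop hormone-coexpressing doublets by
thresholding normalized INS/GCG; and subtract the expected ambient
contribution of genes prominent in empty droplets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import genes as G
from .matrix import CountMatrix, NormalizedMatrix

log = logging.getLogger(__name__)


@dataclass
class QCParams:
    """Thresholds of the QC stage (defaults are the pipeline's canon)."""

    min_genes: int = 200
    max_genes: int = 4000
    max_mito_fraction: float = 0.10
    min_cells_per_gene: int = 3
    size_factor: float = 10_000.0
    #: normalized-log INS/GCG levels above which coexpression marks a doublet
    ins_doublet_threshold: float = 6.5
    gcg_doublet_threshold: float = 5.0
    #: normalized-log level above which a marker counts as "positive"
    #: for the cross-lineage doublet rule
    positive_level: float = 4.0
    #: barcodes with total UMI at or below this define the ambient pool
    ambient_umi_cutoff: float = 100.0
    #: min share of pooled ambient counts for a gene to be called ambient
    ambient_prominence: float = 0.001
    mito_regex: str = r"^MT-"
    marker_table: pd.DataFrame = field(default_factory=G.default_marker_table)

    def validate(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        for name in (
            "min_genes",
            "max_mito_fraction",
            "min_cells_per_gene",
            "size_factor",
            "ins_doublet_threshold",
            "gcg_doublet_threshold",
            "positive_level",
            "ambient_umi_cutoff",
            "ambient_prominence",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["marker_table"] = self.marker_table.to_dict(orient="list")
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "QCParams":
        d = json.loads(Path(path).read_text())
        if "marker_table" in d:
            d["marker_table"] = pd.DataFrame(d["marker_table"])
        return cls(**d)


# ---------------------------------------------------------------------------
# cell / gene filters
# ---------------------------------------------------------------------------

def mito_fraction(counts: CountMatrix, mito_regex: str = r"^MT-") -> np.ndarray:
    """Per-cell fraction of counts from mitochondrially encoded genes."""
    import re

    pat = re.compile(mito_regex)
    mito_mask = np.array([bool(pat.match(s)) for s in counts.gene_symbols])
    totals = counts.totals().astype(float)
    if not mito_mask.any():
        log.warning("no mitochondrial genes matched %r; mito fraction = 0",
                    mito_regex)
        return np.zeros(counts.n_cells)
    mito = np.asarray(counts.X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / totals, 0.0)
    return frac


def filter_cells_genes(
    counts: CountMatrix, params: QCParams
) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply the detected-gene and mitochondrial filters, then the gene
    prevalence filter.

    Returns the filtered matrix and a QC table with one row per *input*
    barcode: n_genes_detected, total_umi, mito_fraction, keep, drop_reason.
    Cells pass with min_genes <= detected <= max_genes (inclusive bounds)
    and mito fraction strictly below max_mito_fraction. Genes are kept when
    detected in at least min_cells_per_gene retained cells.
    """
    params.validate()
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("empty count matrix")
    detected = counts.detected_genes()
    totals = counts.totals()
    mito = mito_fraction(counts, params.mito_regex)

    reasons = np.full(counts.n_cells, "", dtype=object)
    reasons[detected < params.min_genes] = "min_genes"
    reasons[detected > params.max_genes] = "max_genes"
    high_mito = (mito >= params.max_mito_fraction) & (reasons == "")
    reasons[high_mito] = "max_mito_fraction"
    keep = reasons == ""

    qc_table = pd.DataFrame(
        {
            "n_genes_detected": detected,
            "total_umi": totals,
            "mito_fraction": mito,
            "keep": keep,
            "drop_reason": reasons,
        },
        index=pd.Index(counts.barcodes, name="barcode"),
    )

    kept = counts.subset_cells(np.flatnonzero(keep))
    cells_per_gene = np.asarray((kept.X > 0).sum(axis=0)).ravel()
    gene_keep = cells_per_gene >= params.min_cells_per_gene
    out = kept.subset_genes(np.flatnonzero(gene_keep))
    log.info(
        "QC: kept %d/%d cells, %d/%d genes",
        out.n_cells, counts.n_cells, out.n_genes, counts.n_genes,
    )
    return out, qc_table


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_log(counts: CountMatrix, size_factor: float = 10_000.0) -> NormalizedMatrix:
    """ln(count / cell_total * size_factor + 1), sparsity preserved."""
    totals = counts.totals().astype(float)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts cannot be normalized")
    X = counts.X.tocoo(copy=True).astype(float)
    X.data = np.log1p(X.data / totals[X.row] * size_factor)
    return NormalizedMatrix(
        X.tocsr(), counts.barcodes, counts.gene_symbols,
        size_factor, source=counts,
    )


# ---------------------------------------------------------------------------
# hormone-coexpression doublet removal
# ---------------------------------------------------------------------------

def remove_hormone_doublets(
    norm: NormalizedMatrix,
    params: QCParams,
    marker_table: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag hormone-coexpressing doublets on the normalized-log scale.

    Two rules, each recorded per dropped cell:

    * ``ins_gcg_coexpression`` — INS above `ins_doublet_threshold` AND GCG
      above `gcg_doublet_threshold`.
    * ``cross_lineage`` — INS or GCG above `positive_level` together with
      any non-hormone cell-type marker above `positive_level` (the INS+GCG
      pairing itself is governed solely by the first rule, which carries
      its own, stricter thresholds).

    Returns (keep_mask over cells, drops frame with the triggering rule).
    """
    if marker_table is None:
        marker_table = params.marker_table
    for g in ("INS", "GCG"):
        if not norm.has_gene(g):
            raise ValueError(f"{g} missing from the gene set")
    ins = norm.gene_values("INS")
    gcg = norm.gene_values("GCG")

    coexpr = (ins > params.ins_doublet_threshold) & (
        gcg > params.gcg_doublet_threshold
    )

    marker_map = G.marker_table_to_map(marker_table)
    all_markers = set(marker_table["gene_symbol"].unique())
    missing = [g for g in all_markers if not norm.has_gene(g)]
    if missing:
        log.warning("markers absent from matrix, skipped: %s", sorted(missing))

    def _foreign_positive(own_type: str) -> np.ndarray:
        # markers of any *other* lineage above the positive level
        # (the INS+GCG pairing is governed solely by the coexpression rule)
        foreign = [
            g
            for g in all_markers
            if g not in ("INS", "GCG")
            and g not in marker_map.get(own_type, ())
            and norm.has_gene(g)
        ]
        if not foreign:
            return np.zeros(norm.n_cells, bool)
        idx = [norm.gene_index(g) for g in foreign]
        return (
            np.asarray(
                (norm.X[:, idx] > params.positive_level).sum(axis=1)
            ).ravel()
            > 0
        )

    ins_cross = (ins > params.positive_level) & _foreign_positive("beta")
    gcg_cross = (gcg > params.positive_level) & _foreign_positive("alpha")
    cross = (ins_cross | gcg_cross) & ~coexpr

    rules = np.full(norm.n_cells, "", dtype=object)
    rules[cross] = "cross_lineage"
    rules[coexpr] = "ins_gcg_coexpression"
    keep = rules == ""
    drops = pd.DataFrame(
        {"rule": rules[~keep]},
        index=pd.Index(norm.barcodes[~keep], name="barcode"),
    )
    log.info(
        "hormone doublets: dropped %d (coexpression %d, cross-lineage %d)",
        (~keep).sum(), coexpr.sum(), cross.sum(),
    )
    return keep, drops


# ---------------------------------------------------------------------------
# ambient transcript correction
# ---------------------------------------------------------------------------

@dataclass
class AmbientResult:
    """Output of `ambient_correct`."""

    cells: CountMatrix
    empty_barcodes: np.ndarray
    ambient_genes: list[str]
    ambient_profile: pd.Series
    expected_counts: pd.Series  # per-cell expected ambient count per gene


def ambient_correct(raw: CountMatrix, params: QCParams) -> AmbientResult:
    """Estimate ambient transcripts from empty droplets and subtract them.

    Barcodes with total UMI at or below `ambient_umi_cutoff` form the
    ambient pool (and are excluded from the cell set). Genes contributing
    at least `ambient_prominence` of the pooled ambient counts are ambient
    genes. For each ambient gene the expected ambient count per droplet is
    its ambient-pool proportion times the mean empty-droplet total (ambient
    loading is a per-droplet quantity); that expectation is rounded half-up
    and subtracted from every cell's raw count, clipped at zero.
    Non-ambient genes are untouched.
    """
    params.validate()
    totals = raw.totals()
    empty_mask = totals <= params.ambient_umi_cutoff
    if not empty_mask.any():
        log.warning(
            "no barcodes at or below the ambient cutoff (%g); "
            "returning input unchanged", params.ambient_umi_cutoff,
        )
        return AmbientResult(
            cells=raw,
            empty_barcodes=np.array([], dtype=object),
            ambient_genes=[],
            ambient_profile=pd.Series(dtype=float),
            expected_counts=pd.Series(dtype=float),
        )

    pooled = np.asarray(raw.X[empty_mask].sum(axis=0)).ravel().astype(float)
    pool_total = pooled.sum()
    profile = pooled / pool_total if pool_total > 0 else pooled
    prominent = profile >= params.ambient_prominence
    ambient_genes = [
        str(s) for s in np.asarray(raw.gene_symbols)[prominent]
    ]
    mean_empty_total = totals[empty_mask].mean()
    expected = profile * mean_empty_total  # per droplet, per gene

    cells = raw.subset_cells(np.flatnonzero(~empty_mask))
    X = cells.X.tocsc(copy=True)
    sub = np.floor(expected + 0.5).astype(np.int64)  # round half-up
    for j in np.flatnonzero(prominent & (sub > 0)):
        lo, hi = X.indptr[j], X.indptr[j + 1]
        X.data[lo:hi] = np.maximum(X.data[lo:hi] - sub[j], 0)
    X.eliminate_zeros()
    corrected = CountMatrix(
        X.tocsr(), cells.barcodes, cells.gene_ids, cells.gene_symbols
    )
    log.info(
        "ambient: %d empty barcodes, %d ambient genes",
        int(empty_mask.sum()), len(ambient_genes),
    )
    return AmbientResult(
        cells=corrected,
        empty_barcodes=raw.barcodes[empty_mask],
        ambient_genes=ambient_genes,
        ambient_profile=pd.Series(profile, index=raw.gene_symbols),
        expected_counts=pd.Series(expected, index=raw.gene_symbols),
    )
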