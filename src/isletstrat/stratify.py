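"""Combinatorial transcription-factor stratification of islet cells.

A TF is called "detected" in a cell when its normalized expression,
ln(UMI per 10,000 + 1), exceeds 0.5. The joint detection status of a TF
pair (ARX/MAFB in alpha cells, MAFA/MAFB in beta cells) assigns each cell
to one of four groups: None, A-only, B-only, Both. This module computes
the per-cell labels, pooled and per-donor group fractions, dot-plot
summaries (percent detected, mean expression, cross-group z-score),
Mann-Whitney/BH group comparisons, a detected-genes diagnostic for the
dropout argument, and the tissue-imaging analogue that classifies cells
from two-channel marker intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .genes import TF_GROUPS
from .matrix import NormalizedMatrix

log = logging.getLogger(__name__)


@dataclass
class TFPair:
    """A combinatorial TF pair and its detection threshold."""

    gene_a: str
    gene_b: str
    cell_type: str
    threshold: float = 0.5

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("gene_a and gene_b must differ")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class TFGroupResult:
    """Per-cell four-way classification with pooled/per-donor fractions."""

    pair: TFPair
    labels: pd.Series  # index: barcode, values in TF_GROUPS
    pooled_fractions: pd.Series  # index: group
    per_donor_fractions: pd.DataFrame  # donor x group
    n_cells: int

    def group_barcodes(self, group: str) -> np.ndarray:
        return self.labels.index[self.labels == group].to_numpy()


def classify_combinatorial(
    a: np.ndarray, b: np.ndarray, threshold: float, detection: str = "threshold"
) -> np.ndarray:
    """Four-way group labels from two expression vectors.

    detection="threshold": detected iff value > threshold (values exactly
    at the threshold count as low — a conservative call).
    detection="nonzero": detected iff value > 0.
    """
    if detection == "threshold":
        a_on, b_on = a > threshold, b > threshold
    elif detection == "nonzero":
        a_on, b_on = a > 0, b > 0
    else:
        raise ValueError(f"unknown detection mode {detection!r}")
    out = np.full(len(a), TF_GROUPS[0], dtype=object)
    out[a_on & ~b_on] = TF_GROUPS[1]
    out[~a_on & b_on] = TF_GROUPS[2]
    out[a_on & b_on] = TF_GROUPS[3]
    return out


def binarize_and_classify(
    norm: NormalizedMatrix,
    cell_table: pd.DataFrame,
    pair: TFPair,
    detection: str = "threshold",
) -> TFGroupResult:
    """Classify cells of the pair's target type into the four TF groups.

    `cell_table` (index: barcode) must carry `cell_type` and, for per-donor
    fractions, `donor`. Fractions are reported pooled and per donor; each
    donor's fractions sum to 1.
    """
    for g in (pair.gene_a, pair.gene_b):
        if not norm.has_gene(g):
            raise ValueError(f"TF gene {g!r} absent from matrix")
    cells = cell_table[cell_table["cell_type"] == pair.cell_type]
    if len(cells) == 0:
        raise ValueError(f"no cells of type {pair.cell_type!r}")
    pos = pd.Series(np.arange(norm.n_cells), index=norm.barcodes)
    idx = pos.reindex(cells.index).dropna().astype(int)
    a = norm.gene_values(pair.gene_a)[idx.to_numpy()]
    b = norm.gene_values(pair.gene_b)[idx.to_numpy()]
    labels = pd.Series(
        classify_combinatorial(a, b, pair.threshold, detection),
        index=idx.index, name="tf_group",
    )
    pooled = (
        labels.value_counts(normalize=True)
        .reindex(TF_GROUPS, fill_value=0.0)
        .rename("fraction")
    )
    if "donor" in cells.columns:
        per_donor = (
            pd.crosstab(cells.loc[labels.index, "donor"], labels, normalize="index")
            .reindex(columns=TF_GROUPS, fill_value=0.0)
        )
    else:
        per_donor = pd.DataFrame(columns=list(TF_GROUPS))
    return TFGroupResult(
        pair=pair,
        labels=labels,
        pooled_fractions=pooled,
        per_donor_fractions=per_donor,
        n_cells=len(labels),
    )


# ---------------------------------------------------------------------------
# dot-plot summaries
# ---------------------------------------------------------------------------

def dotplot_stats(
    norm: NormalizedMatrix,
    groups: TFGroupResult,
    gene_panel: list[str],
) -> pd.DataFrame:
    """Percent-detected, group mean expression, and cross-group z-score.

    One row per gene x group. `pct_detected` is the fraction of the
    group's cells with any transcript (raw count > 0, equivalently a
    nonzero normalized value). The z-score standardizes the four group
    means per gene with the sample (n-1) standard deviation; genes with
    identical means across groups (or undetected everywhere) get z = 0 and
    `undetected` flags the latter. Empty groups are omitted.
    """
    panel = [g for g in gene_panel if norm.has_gene(g)]
    skipped = [g for g in gene_panel if not norm.has_gene(g)]
    if skipped:
        log.warning("panel genes absent from matrix, skipped: %s", skipped)
    pos = pd.Series(np.arange(norm.n_cells), index=norm.barcodes)
    rows = []
    for gene in panel:
        vals = norm.gene_values(gene)
        per_group = {}
        for grp in TF_GROUPS:
            bcs = groups.group_barcodes(grp)
            if len(bcs) == 0:
                continue
            v = vals[pos.reindex(bcs).to_numpy(dtype=int)]
            per_group[grp] = v
        means = {g: float(v.mean()) for g, v in per_group.items()}
        mvec = np.array(list(means.values()))
        sd = mvec.std(ddof=1) if len(mvec) > 1 else 0.0
        undetected = bool(np.all(mvec == 0))
        for grp, v in per_group.items():
            z = (means[grp] - mvec.mean()) / sd if sd > 0 else 0.0
            rows.append(
                {
                    "gene": gene,
                    "group": grp,
                    "n_cells": len(v),
                    "pct_detected": float((v > 0).mean()),
                    "mean_expr": means[grp],
                    "z_score": float(z),
                    "undetected": undetected,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group-wise gene comparisons
# ---------------------------------------------------------------------------

def compare_groups(
    norm: NormalizedMatrix,
    groups: TFGroupResult,
    gene_panel: list[str],
    reference: str = "Both",
    scheme: str = "both_vs_rest",
    bh_family: str = "joint",
) -> pd.DataFrame:
    """Mann-Whitney tests of each panel gene between TF groups.

    scheme="both_vs_rest" compares `reference` against each other
    non-empty group; scheme="all_pairs" runs every pairwise comparison.
    BH adjustment spans the full gene x comparison family by default
    (bh_family="joint") or each comparison separately ("per_comparison").
    """
    panel = [g for g in gene_panel if norm.has_gene(g)]
    pos = pd.Series(np.arange(norm.n_cells), index=norm.barcodes)
    group_idx = {
        grp: pos.reindex(groups.group_barcodes(grp)).to_numpy(dtype=int)
        for grp in TF_GROUPS
        if len(groups.group_barcodes(grp)) > 0
    }
    present = list(group_idx)
    if len(present) < 2:
        raise ValueError("need at least two non-empty groups")
    if scheme == "both_vs_rest":
        if reference not in group_idx:
            raise ValueError(f"reference group {reference!r} is empty")
        comparisons = [(reference, g) for g in present if g != reference]
    elif scheme == "all_pairs":
        comparisons = [
            (a, b) for i, a in enumerate(present) for b in present[i + 1:]
        ]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rows = []
    for gene in panel:
        vals = norm.gene_values(gene)
        for ga, gb in comparisons:
            x, y = vals[group_idx[ga]], vals[group_idx[gb]]
            u, p = stats.mann_whitney_u(x, y)
            rows.append(
                {
                    "gene": gene,
                    "comparison": f"{ga}_vs_{gb}",
                    "n_a": len(x),
                    "n_b": len(y),
                    "median_a": float(np.median(x)),
                    "median_b": float(np.median(y)),
                    "mean_a": float(x.mean()),
                    "mean_b": float(y.mean()),
                    "u_statistic": u,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    if bh_family == "joint":
        out["p_adjusted"] = stats.bh_adjust(out["p_value"].to_numpy())
    elif bh_family == "per_comparison":
        out["p_adjusted"] = np.nan
        for _, idx in out.groupby("comparison").groups.items():
            out.loc[idx, "p_adjusted"] = stats.bh_adjust(
                out.loc[idx, "p_value"].to_numpy()
            )
    else:
        raise ValueError(f"unknown bh_family {bh_family!r}")
    out["stars"] = [stats.significance_stars(p) for p in out["p_adjusted"]]
    return out


# ---------------------------------------------------------------------------
# detected-genes diagnostic (dropout argument)
# ---------------------------------------------------------------------------

def detected_genes_by_level(
    norm: NormalizedMatrix,
    tf_gene: str,
    threshold: float = 0.5,
    cell_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Detected-genes-per-cell summaries for TF-low vs TF-high cells.

    Strata: cells with normalized `tf_gene` expression at or below the
    threshold ("low") vs above it ("high"). Reports n, median, quartiles,
    and the fraction of cells with more than 1000 detected genes. Empty
    strata are absent from the output.
    """
    if not norm.has_gene(tf_gene):
        raise ValueError(f"gene {tf_gene!r} missing from matrix")
    detected = norm.detected_genes()
    tf = norm.gene_values(tf_gene)
    if cell_mask is not None:
        detected, tf = detected[cell_mask], tf[cell_mask]
    rows = {}
    for name, mask in (("low", tf <= threshold), ("high", tf > threshold)):
        if not mask.any():
            continue
        d = detected[mask]
        rows[name] = {
            "n_cells": int(mask.sum()),
            "median": float(np.median(d)),
            "q25": float(np.percentile(d, 25)),
            "q75": float(np.percentile(d, 75)),
            "frac_gt_1000": float((d > 1000).mean()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# tissue-intensity analogue
# ---------------------------------------------------------------------------

INTENSITY_CLASSES = ("lo/lo", "hi/lo", "lo/hi", "hi/hi")


@dataclass
class IntensityResult:
    labels: pd.Series
    pooled_fractions: pd.Series
    per_donor_fractions: pd.DataFrame
    n_cells: int
    n_excluded: int


def classify_intensity(
    intensity_table: pd.DataFrame,
    thresholds: tuple[float, float],
    marker_cols: tuple[str, str] = ("marker_a", "marker_b"),
    donor_col: str = "donor",
) -> IntensityResult:
    """Four-way hi/lo classification of per-cell marker intensities.

    Each marker gets one fixed threshold (held constant across all islets
    of a tissue); a cell is "hi" for a marker when its intensity exceeds
    the threshold. Cells with missing intensities are excluded (counted).
    """
    ca, cb = marker_cols
    ta, tb = thresholds
    valid = intensity_table[[ca, cb]].notna().all(axis=1)
    n_excluded = int((~valid).sum())
    if n_excluded:
        log.info("classify_intensity: excluded %d cells with missing values",
                 n_excluded)
    sub = intensity_table[valid]
    a_hi = sub[ca].to_numpy() > ta
    b_hi = sub[cb].to_numpy() > tb
    lab = np.full(len(sub), INTENSITY_CLASSES[0], dtype=object)
    lab[a_hi & ~b_hi] = INTENSITY_CLASSES[1]
    lab[~a_hi & b_hi] = INTENSITY_CLASSES[2]
    lab[a_hi & b_hi] = INTENSITY_CLASSES[3]
    labels = pd.Series(lab, index=sub.index, name="intensity_class")
    pooled = (
        labels.value_counts(normalize=True)
        .reindex(INTENSITY_CLASSES, fill_value=0.0)
        .rename("fraction")
    )
    if donor_col in sub.columns:
        per_donor = pd.crosstab(
            sub[donor_col], labels, normalize="index"
        ).reindex(columns=INTENSITY_CLASSES, fill_value=0.0)
    else:
        per_donor = pd.DataFrame(columns=list(INTENSITY_CLASSES))
    return IntensityResult(
        labels=labels,
        pooled_fractions=pooled,
        per_donor_fractions=per_donor,
        n_cells=len(labels),
        n_excluded=n_excluded,
    )
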