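"""Bulk vs single-cell congruency analyses.

Three pieces: pseudobulk aggregation (per-gene mean UMI over a cell type),
detection-filtered expression correlation between a bulk TPM profile and
the matched pseudobulk, and paired alpha-vs-beta differential-expression
concordance (bulk z-score DE against single-cell Mann-Whitney DE, with the
correlation of the two log2 fold-change vectors on jointly significant
genes and the count of genes regulated in opposite directions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .matrix import CountMatrix, NormalizedMatrix

log = logging.getLogger(__name__)


def pseudobulk(
    counts: CountMatrix,
    cell_table: pd.DataFrame,
    cell_type: str,
) -> pd.Series:
    """Per-gene mean raw UMI across cells of one type."""
    cells = cell_table[cell_table["cell_type"] == cell_type]
    if len(cells) == 0:
        raise ValueError(f"no cells of type {cell_type!r}")
    pos = pd.Series(np.arange(counts.n_cells), index=counts.barcodes)
    idx = pos.reindex(cells.index).dropna().astype(int).to_numpy()
    if idx.size == 0:
        raise ValueError(f"no cells of type {cell_type!r} present in matrix")
    means = np.asarray(counts.X[idx].mean(axis=0)).ravel()
    return pd.Series(means, index=counts.gene_symbols,
                     name=f"{cell_type}_mean_umi")


@dataclass
class ConcordanceResult:
    r: float
    p: float
    n_genes: int
    genes: list[str]


def expression_concordance(
    bulk: pd.Series,
    pseudo: pd.Series,
    bulk_min_log2tpm: float = 1.0,
    sc_min_umi: float = 1.0,
) -> ConcordanceResult:
    """Pearson correlation of log-transformed bulk TPM vs pseudobulk UMI.

    Genes must pass both detection filters: log2(TPM) > bulk_min_log2tpm
    and mean UMI > sc_min_umi. Correlation is computed on log2 values.
    """
    shared = bulk.index.intersection(pseudo.index)
    b = bulk.loc[shared].astype(float)
    s = pseudo.loc[shared].astype(float)
    with np.errstate(divide="ignore"):
        mask = (np.log2(b.where(b > 0)) > bulk_min_log2tpm) & (s > sc_min_umi)
    mask = mask.fillna(False)
    genes = shared[mask].tolist()
    if len(genes) < 3:
        raise ValueError(
            f"only {len(genes)} genes pass both detection filters (need >= 3)"
        )
    r, p = sps.pearsonr(np.log2(b[mask]), np.log2(s[mask]))
    return ConcordanceResult(r=float(r), p=float(p), n_genes=len(genes),
                             genes=genes)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def bulk_de(
    bulk_a: pd.Series,
    bulk_b: pd.Series,
    pseudocount: float = 1.0,
    fc_cutoff: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bulk DE by the fold-change + z-score rule.

    log2FC = log2((TPM_a + pc) / (TPM_b + pc)); a z-score standardizes
    each gene's log2FC against the distribution of log2FCs across genes
    (the single-replicate normal approximation), two-sided normal p, BH
    adjustment. A gene is significant when |log2FC| >= fc_cutoff and
    adjusted p < alpha.
    """
    shared = bulk_a.index.intersection(bulk_b.index)
    a = bulk_a.loc[shared].astype(float)
    b = bulk_b.loc[shared].astype(float)
    log2fc = np.log2((a + pseudocount) / (b + pseudocount))
    sd = log2fc.std(ddof=1)
    if sd == 0:
        z = pd.Series(0.0, index=shared)
    else:
        z = (log2fc - log2fc.mean()) / sd
    p = 2.0 * sps.norm.sf(np.abs(z))
    p_adj = stats.bh_adjust(p)
    out = pd.DataFrame(
        {
            "gene": shared,
            "log2fc": log2fc.to_numpy(),
            "z": z.to_numpy(),
            "p_value": p,
            "p_adjusted": p_adj,
        }
    ).set_index("gene")
    out["significant"] = (out["log2fc"].abs() >= fc_cutoff) & (
        out["p_adjusted"] < alpha
    )
    return out


def sc_de(
    counts: CountMatrix,
    norm: NormalizedMatrix,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    pseudocount: float = 1.0,
    fc_cutoff: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Single-cell DE: mean-UMI log-ratio with Mann-Whitney p and BH.

    log2FC = log2((mean_a + pc) / (mean_b + pc)) on raw UMI means; the
    per-gene test is a two-sided Mann-Whitney on normalized values
    (normal approximation with tie correction — droplet counts are heavily
    tied).
    """
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both cell sets must be non-empty")
    mean_a = np.asarray(counts.X[mask_a].mean(axis=0)).ravel()
    mean_b = np.asarray(counts.X[mask_b].mean(axis=0)).ravel()
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    A = np.asarray(norm.X[mask_a].todense(), float)
    B = np.asarray(norm.X[mask_b].todense(), float)
    _, p = stats.mann_whitney_matrix(A, B)
    p_adj = stats.bh_adjust(p)
    out = pd.DataFrame(
        {
            "gene": counts.gene_symbols,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_value": p,
            "p_adjusted": p_adj,
        }
    ).set_index("gene")
    out["significant"] = (out["log2fc"].abs() >= fc_cutoff) & (
        out["p_adjusted"] < alpha
    )
    return out


@dataclass
class DEConcordance:
    bulk: pd.DataFrame
    sc: pd.DataFrame
    fc_correlation: float
    n_joint_significant: int
    n_discordant: int
    joint_genes: list[str]


def de_and_fc_concordance(
    bulk_a: pd.Series,
    bulk_b: pd.Series,
    counts: CountMatrix,
    norm: NormalizedMatrix,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    pseudocount: float = 1.0,
    fc_pseudocount: float | None = None,
) -> DEConcordance:
    """Paired bulk/single-cell DE with fold-change concordance.

    `fc_pseudocount` controls the pseudocount used for the *correlated*
    fold-change vectors (default: same as `pseudocount`). With
    fc_pseudocount=0, genes with a nonpositive mean on either side are
    excluded and the correlation is exact on noise-free paired data.
    """
    if fc_pseudocount is None:
        fc_pseudocount = pseudocount
    b = bulk_de(bulk_a, bulk_b, pseudocount=pseudocount)
    s = sc_de(counts, norm, mask_a, mask_b, pseudocount=pseudocount)
    shared = b.index.intersection(s.index)
    joint = shared[
        b.loc[shared, "significant"].to_numpy()
        & s.loc[shared, "significant"].to_numpy()
    ]
    if len(joint) == 0:
        log.warning("no jointly significant genes; concordance undefined")
        return DEConcordance(b, s, float("nan"), 0, 0, [])

    ba = bulk_a.loc[joint].astype(float)
    bb = bulk_b.loc[joint].astype(float)
    sa = s.loc[joint, "mean_a"]
    sb = s.loc[joint, "mean_b"]
    with np.errstate(divide="ignore"):
        fc_bulk = np.log2((ba + fc_pseudocount) / (bb + fc_pseudocount))
        fc_sc = np.log2(
            (sa + fc_pseudocount) / (sb + fc_pseudocount)
        )
    finite = np.isfinite(fc_bulk) & np.isfinite(fc_sc)
    fc_bulk, fc_sc = fc_bulk[finite], fc_sc[finite]
    genes = joint[finite.to_numpy()].tolist()
    if len(genes) >= 3 and fc_bulk.std() > 0 and fc_sc.std() > 0:
        r = float(sps.pearsonr(fc_bulk, fc_sc)[0])
    else:
        r = float("nan")
    discordant = int(np.sum(np.sign(fc_bulk) * np.sign(fc_sc) < 0))
    return DEConcordance(
        bulk=b,
        sc=s,
        fc_correlation=r,
        n_joint_significant=len(genes),
        n_discordant=discordant,
        joint_genes=genes,
    )
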