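"""Dimensionality reduction, graph clustering, and cell-type annotation.

Pipeline: variance-stabilized HVG selection -> per-gene scaling with linear
regression-out of nuisance covariates (mitochondrial fraction by default)
-> PCA -> kNN graph -> Louvain community detection. Clusters are annotated
by marker-gene enrichment (argmax of cross-cluster z-scored marker means);
rare endocrine types hidden inside a parent cluster are relabeled with an
explicit thresholded rule.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from . import genes as G
from .matrix import NormalizedMatrix

log = logging.getLogger(__name__)


@dataclass
class ClusterParams:
    n_hvg: int = 2000
    n_pcs: int = 20
    resolution: float = 0.6
    knn_k: int = 20
    regress_out: tuple[str, ...] = ("mito_fraction",)
    scale_clip: float = 10.0
    n_dispersion_bins: int = 20

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.n_pcs > self.n_hvg:
            raise ValueError("n_pcs must be <= n_hvg")
        for name in ("n_hvg", "n_pcs", "knn_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def highly_variable_genes(norm: NormalizedMatrix, n_top: int,
                          n_bins: int = 20) -> np.ndarray:
    """Indices of the top-n genes by mean-binned dispersion z-score.

    Dispersion = variance / mean of the normalized values; genes are binned
    by mean expression and the dispersion is z-scored within each bin, so
    high- and low-expressed genes compete fairly.
    """
    X = norm.X
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    n_top = min(n_top, X.shape[1])
    order = pd.Series(mean).rank(method="first")
    bins = pd.qcut(order, q=min(n_bins, X.shape[1]), labels=False,
                   duplicates="drop")
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        m = bins == b
        mu, sd = disp[m].mean(), disp[m].std(ddof=1) if m.sum() > 1 else 0.0
        z[m] = (disp[m] - mu) / sd if sd and sd > 0 else 0.0
    return np.argsort(-z, kind="stable")[:n_top]


def _scale_with_regression(
    X: np.ndarray, covariates: pd.DataFrame | None, clip: float
) -> np.ndarray:
    """Residualize on covariates, then center/scale columns; clip extremes.

    Zero-variance columns are dropped from scaling (set to 0) with a log
    message rather than an error.
    """
    if covariates is not None and covariates.shape[1] > 0:
        design = np.column_stack(
            [np.ones(len(X))] + [covariates[c].to_numpy(float)
                                 for c in covariates]
        )
        beta, *_ = np.linalg.lstsq(design, X, rcond=None)
        X = X - design @ beta
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        log.info("dropping %d zero-variance genes from scaling",
                 int(degenerate.sum()))
    sd = np.where(degenerate, 1.0, sd)
    Z = (X - mu) / sd
    Z[:, degenerate] = 0.0
    return np.clip(Z, -clip, clip)


def embed_and_cluster(
    norm: NormalizedMatrix,
    params: ClusterParams,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """HVG -> scale (regress out covariates) -> PCA -> kNN -> Louvain.

    `covariates` supplies per-cell nuisance columns named in
    `params.regress_out` (missing ones are skipped with a warning).
    Returns (cluster labels, PCA coordinates); deterministic given seed.
    """
    params.validate()
    if norm.n_cells < 2 * params.n_pcs:
        raise ValueError(
            f"need at least {2 * params.n_pcs} cells for {params.n_pcs} PCs"
        )
    hvg = highly_variable_genes(norm, params.n_hvg, params.n_dispersion_bins)
    X = np.asarray(norm.X[:, hvg].todense(), dtype=float)

    cov = None
    if params.regress_out and covariates is not None:
        have = [c for c in params.regress_out if c in covariates.columns]
        missing = set(params.regress_out) - set(have)
        if missing:
            log.warning("covariates not provided, skipped: %s", sorted(missing))
        if have:
            cov = covariates[have]
    elif params.regress_out:
        log.warning("no covariate table given; regress_out skipped")

    Z = _scale_with_regression(X, cov, params.scale_clip)
    n_pcs = min(params.n_pcs, min(Z.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(Z)

    k = min(params.knn_k, norm.n_cells - 1)
    A = kneighbors_graph(pcs, n_neighbors=k, mode="connectivity",
                         include_self=False)
    A = A.maximum(A.T)
    coo = sp.triu(A, k=1).tocoo()
    graph = ig.Graph(
        n=A.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist()))
    )
    ig.set_random_number_generator(_pyrandom.Random(int(seed)))
    part = graph.community_multilevel(resolution=params.resolution)
    labels = np.asarray(part.membership, dtype=int)
    log.info("Louvain: %d clusters at resolution %.2f",
             labels.max() + 1, params.resolution)
    return labels, pcs


def annotate_clusters(
    clusters: np.ndarray,
    norm: NormalizedMatrix,
    marker_table: pd.DataFrame | None = None,
) -> dict[int, str]:
    """Label each cluster by its most enriched marker set.

    For every marker gene the cluster means are z-scored across clusters;
    a cluster's score for a cell type is the mean z over that type's
    markers. Ties go to the type with more markers detected in the
    cluster, then lexicographically (warned).
    """
    if marker_table is None:
        marker_table = G.default_marker_table()
    marker_map = G.marker_table_to_map(marker_table)
    cluster_ids = np.unique(clusters)

    all_markers = [
        g for gs in marker_map.values() for g in gs if norm.has_gene(g)
    ]
    skipped = [
        g for gs in marker_map.values() for g in gs if not norm.has_gene(g)
    ]
    if skipped:
        log.warning("markers absent from matrix, skipped: %s", skipped)
    cols = {g: norm.gene_index(g) for g in all_markers}

    means = np.zeros((len(cluster_ids), len(all_markers)))
    for ci, c in enumerate(cluster_ids):
        sub = norm.X[clusters == c][:, list(cols.values())]
        means[ci] = np.asarray(sub.mean(axis=0)).ravel()
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1) if len(cluster_ids) > 1 else np.ones(
        means.shape[1]
    )
    sd = np.where(sd > 0, sd, 1.0)
    z = (means - mu) / sd
    zcols = {g: j for j, g in enumerate(all_markers)}

    mapping: dict[int, str] = {}
    for ci, c in enumerate(cluster_ids):
        scores = {}
        detected = {}
        for ct, gs in marker_map.items():
            present = [g for g in gs if g in zcols]
            if not present:
                continue
            scores[ct] = float(np.mean([z[ci, zcols[g]] for g in present]))
            detected[ct] = int(sum(means[ci, zcols[g]] > 0 for g in present))
        best = max(scores.values())
        tied = sorted(
            [ct for ct, s in scores.items() if np.isclose(s, best)]
        )
        if len(tied) > 1:
            tied.sort(key=lambda ct: (-detected[ct], ct))
            log.warning(
                "cluster %d: marker-score tie between %s; chose %s",
                c, tied, tied[0],
            )
        mapping[int(c)] = tied[0]
    return mapping


def select_rare_cells(
    cell_table: pd.DataFrame,
    norm: NormalizedMatrix,
    gene: str,
    threshold: float,
    parent_type: str,
    new_type: str,
) -> pd.DataFrame:
    """Relabel cells of `parent_type` positive for `gene` as `new_type`.

    Replaces manual lasso selection of rare endocrine cells (e.g. PPY+
    gamma and GHRL+ epsilon cells inside the delta cluster) with an
    explicit normalized-expression threshold.
    """
    if not norm.has_gene(gene):
        raise ValueError(f"gene {gene!r} missing from matrix")
    values = pd.Series(norm.gene_values(gene), index=norm.barcodes)
    out = cell_table.copy()
    mask = (out["cell_type"] == parent_type) & (
        values.reindex(out.index).to_numpy() > threshold
    )
    out.loc[mask, "cell_type"] = new_type
    log.info("relabeled %d %s cells as %s (%s > %g)",
             int(mask.sum()), parent_type, new_type, gene, threshold)
    return out
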