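"""Sparse count-matrix containers and 10x-style triplet I/O.

`CountMatrix` holds raw UMI counts as barcodes x genes (cells in rows, the
in-memory orientation used throughout the package); on disk the Matrix
Market file follows the 10x convention of genes x barcodes and is
transposed on read/write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

log = logging.getLogger(__name__)


def _as_csr(X) -> sp.csr_matrix:
    X = sp.csr_matrix(X)
    X.eliminate_zeros()
    return X


@dataclass
class CountMatrix:
    """Raw UMI counts, barcodes (cells) x genes.

    Attributes
    ----------
    X : scipy.sparse.csr_matrix
        Nonnegative integer counts.
    barcodes, gene_ids, gene_symbols : np.ndarray of str
        Unique barcode ids; unique gene ids; gene symbols (symbols may
        repeat in real references, ids never do).
    """

    X: sp.csr_matrix
    barcodes: np.ndarray
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    _sym_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.X = _as_csr(self.X)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        if self.X.shape != (len(self.barcodes), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.gene_ids)} genes"
            )
        if len(self.gene_symbols) != len(self.gene_ids):
            raise ValueError("gene_symbols and gene_ids length mismatch")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("negative counts")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        self._sym_index = None

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def totals(self) -> np.ndarray:
        """Total UMI per barcode."""
        return np.asarray(self.X.sum(axis=1)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Number of genes with count > 0 per barcode."""
        return np.diff(self.X.indptr)

    def gene_index(self, symbol: str) -> int:
        """Column index of a gene symbol (first occurrence)."""
        if self._sym_index is None:
            self._sym_index = {}
            for i, s in enumerate(self.gene_symbols):
                self._sym_index.setdefault(s, i)
        try:
            return self._sym_index[symbol]
        except KeyError:
            raise KeyError(f"gene symbol {symbol!r} not in matrix") from None

    def has_gene(self, symbol: str) -> bool:
        try:
            self.gene_index(symbol)
            return True
        except KeyError:
            return False

    def gene_column(self, symbol: str) -> np.ndarray:
        """Dense counts of one gene across barcodes."""
        j = self.gene_index(symbol)
        return np.asarray(self.X[:, j].todense()).ravel()

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.X[idx], self.barcodes[idx], self.gene_ids, self.gene_symbols
        )

    def subset_genes(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.X[:, idx],
            self.barcodes,
            self.gene_ids[idx],
            self.gene_symbols[idx],
        )

    # -- interop ---------------------------------------------------------
    def to_anndata(self):
        """Convert to an AnnData (cells x genes) for downstream toolchains."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.X.copy(),
            obs=pd.DataFrame(index=pd.Index(self.barcodes, name="barcode")),
            var=pd.DataFrame(
                {"gene_symbol": self.gene_symbols},
                index=pd.Index(self.gene_ids, name="gene_id"),
            ),
        )
        return adata

    # -- 10x-style triplet I/O -------------------------------------------
    def write_10x(self, outdir) -> None:
        """Write matrix.mtx (genes x barcodes), features.tsv, barcodes.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(
            str(outdir / "matrix.mtx"),
            sp.coo_matrix(self.X.T),
            field="integer",
        )
        pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "gene_symbol": self.gene_symbols,
                "feature_type": "Gene Expression",
            }
        ).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(self.barcodes).to_csv(
            outdir / "barcodes.tsv", header=False, index=False
        )

    @classmethod
    def read_10x(cls, indir) -> "CountMatrix":
        indir = Path(indir)
        X = sp.csr_matrix(mmread(str(indir / "matrix.mtx")).T)
        feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
        barcodes = pd.read_csv(indir / "barcodes.tsv", header=None)[0].to_numpy()
        return cls(
            X,
            barcodes,
            feats[0].to_numpy(),
            feats[1 if feats.shape[1] > 1 else 0].to_numpy(),
        )


@dataclass
class NormalizedMatrix:
    """Library-size normalized, log-transformed expression.

    Entry (i, j) = ln(count_ij / total_i * size_factor + 1); sparsity is
    preserved (zeros stay zeros).
    """

    X: sp.csr_matrix
    barcodes: np.ndarray
    gene_symbols: np.ndarray
    size_factor: float
    source: CountMatrix | None = field(default=None, repr=False, compare=False)
    _sym_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.X = sp.csr_matrix(self.X)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self._sym_index = None

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def gene_index(self, symbol: str) -> int:
        if self._sym_index is None:
            self._sym_index = {}
            for i, s in enumerate(self.gene_symbols):
                self._sym_index.setdefault(s, i)
        try:
            return self._sym_index[symbol]
        except KeyError:
            raise KeyError(f"gene symbol {symbol!r} not in matrix") from None

    def has_gene(self, symbol: str) -> bool:
        try:
            self.gene_index(symbol)
            return True
        except KeyError:
            return False

    def gene_values(self, symbol: str) -> np.ndarray:
        """Dense normalized values of one gene across cells."""
        j = self.gene_index(symbol)
        return np.asarray(self.X[:, j].todense()).ravel()

    def detected_genes(self) -> np.ndarray:
        return np.diff(self.X.indptr)

    def subset_cells(self, idx) -> "NormalizedMatrix":
        idx = np.asarray(idx)
        src = self.source.subset_cells(idx) if self.source is not None else None
        return NormalizedMatrix(
            self.X[idx],
            self.barcodes[idx],
            self.gene_symbols,
            self.size_factor,
            source=src,
        )
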