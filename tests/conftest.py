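"""Shared fixtures: small synthetic datasets and hand-built matrices."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import isletstrat as ist
from isletstrat.matrix import CountMatrix
from isletstrat.simulate import default_census


@pytest.fixture(scope="session")
def small_sim():
    """A modest multi-type dataset with doublets, ambient RNA, empties."""
    cfg = ist.SimConfig(
        seed=7,
        n_cells_per_type=default_census(1500),
        n_empty_droplets=300,
    )
    counts, truth = ist.generate_dataset(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def clean_alpha_sim():
    """5000 alpha cells, no ambient RNA / doublets / empties."""
    cfg = ist.SimConfig(
        seed=13,
        n_cells_per_type={"alpha": 5000},
        ambient_fraction=0.0,
        doublet_rate=0.0,
        n_empty_droplets=0,
    )
    counts, truth = ist.generate_dataset(cfg)
    return cfg, counts, truth


@pytest.fixture
def tiny_counts():
    """A hand-built 4-cell x 5-gene matrix with MT and hormone genes."""
    X = sp.csr_matrix(
        np.array(
            [
                [10, 0, 5, 1, 4],
                [0, 8, 0, 2, 0],
                [3, 3, 3, 3, 3],
                [0, 0, 0, 0, 1],
            ]
        )
    )
    return CountMatrix(
        X,
        barcodes=np.array([f"C{i}" for i in range(4)], object),
        gene_ids=np.array([f"G{i}" for i in range(5)], object),
        gene_symbols=np.array(["INS", "GCG", "MT-CO1", "SST", "KRT19"], object),
    )


def make_norm(values, gene_symbols, barcodes=None):
    """NormalizedMatrix straight from a dense array of normalized values."""
    values = np.asarray(values, dtype=float)
    if barcodes is None:
        barcodes = [f"C{i}" for i in range(values.shape[0])]
    return ist.NormalizedMatrix(
        sp.csr_matrix(values),
        np.array(barcodes, object),
        np.array(gene_symbols, object),
        size_factor=10_000.0,
    )


def cell_table_for(norm, cell_type="alpha", donors=None):
    """Minimal cell table matching a NormalizedMatrix's barcodes."""
    table = pd.DataFrame(
        {"cell_type": cell_type}, index=pd.Index(norm.barcodes, name="barcode")
    )
    if donors is not None:
        table["donor"] = donors
    return table
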