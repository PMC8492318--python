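"""Default gene sets for the human islet model.

Cell-type marker genes, the two combinatorial transcription-factor (TF)
pairs (ARX/MAFB for alpha cells, MAFA/MAFB for beta cells), a panel of
functional "program" genes (glucose sensing, ion flux, vesicle trafficking,
exocytosis) whose expression is coupled to joint TF detection, and
mitochondrially encoded genes used for QC.

These defaults are user-overridable everywhere they are consumed; marker
tables can be loaded from TSV (columns: cell_type, gene_symbol).
"""

from __future__ import annotations

import pandas as pd

CELL_TYPES = (
    "alpha",
    "beta",
    "delta",
    "gamma",
    "epsilon",
    "acinar",
    "ductal",
    "endothelial",
    "stellate",
    "immune",
)

ENDOCRINE_TYPES = ("alpha", "beta", "delta", "gamma", "epsilon")

#: canonical identity markers per islet cell type
MARKER_MAP: dict[str, tuple[str, ...]] = {
    "alpha": ("GCG", "TM4SF4", "IRX2"),
    "beta": ("INS", "IAPP", "NKX6-1"),
    "delta": ("SST", "HHEX"),
    "gamma": ("PPY",),
    "epsilon": ("GHRL",),
    "acinar": ("PRSS1", "CPA1"),
    "ductal": ("KRT19", "SPP1"),
    "endothelial": ("PECAM1", "PLVAP"),
    "stellate": ("COL1A1", "PDGFRB"),
    "immune": ("PTPRC", "SDS"),
}

#: hormone / dominant marker per endocrine type (very high expression)
HORMONE_GENES = {
    "alpha": "GCG",
    "beta": "INS",
    "delta": "SST",
    "gamma": "PPY",
    "epsilon": "GHRL",
}

#: combinatorial TF pair per stratifiable cell type: (gene_a, gene_b)
TF_PAIRS: dict[str, tuple[str, str]] = {
    "alpha": ("ARX", "MAFB"),
    "beta": ("MAFA", "MAFB"),
}

TF_GENES = ("ARX", "MAFA", "MAFB")

#: the four combinatorial detection groups, in canonical order
TF_GROUPS = ("None", "A-only", "B-only", "Both")

#: functional program genes elevated with joint TF detection
PROGRAM_GENES = (
    "RFX6",
    "PAX6",
    "NEUROD1",
    "ISL1",
    "PDX1",
    "PCSK1",
    "ACLY",
    "PKM",
    "GSTA4",
    "GPX3",
    "G6PC2",
    "KCTD12",
    "KCNK16",
    "KCNJ6",
    "ABCC8",
    "VAMP2",
    "SYT7",
    "PCLO",
    "TSPAN7",
    "RGS9",
)

MITO_GENES = (
    "MT-CO1",
    "MT-CO2",
    "MT-CO3",
    "MT-ND1",
    "MT-ND2",
    "MT-ND4",
    "MT-CYB",
    "MT-ATP6",
)


def default_marker_table() -> pd.DataFrame:
    """Marker table as a two-column frame (cell_type, gene_symbol)."""
    rows = [
        {"cell_type": ct, "gene_symbol": g}
        for ct, gs in MARKER_MAP.items()
        for g in gs
    ]
    return pd.DataFrame(rows)


def marker_table_to_map(table: pd.DataFrame) -> dict[str, tuple[str, ...]]:
    """Convert a (cell_type, gene_symbol) frame back to a mapping."""
    out: dict[str, tuple[str, ...]] = {}
    for ct, sub in table.groupby("cell_type", sort=False):
        out[str(ct)] = tuple(sub["gene_symbol"])
    return out
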