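"""Electrophysiology comparisons across TF-defined beta-cell groups.

Consumes Patch-Seq-style per-cell tables (a TF group label plus
electrophysiological features: cell size, exocytosis, Ca2+ currents and
conductance, Na+ current) and tests each feature between the
Both-detected group and every other group with the shared Mann-Whitney /
Benjamini-Hochberg machinery.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stats
from .genes import TF_GROUPS
from .simulate import EPHYS_FEATURES

log = logging.getLogger(__name__)

DEFAULT_FEATURES = tuple(EPHYS_FEATURES)


def compare_ephys_groups(
    table: pd.DataFrame,
    features: tuple[str, ...] | None = None,
    reference: str = "Both",
    group_col: str = "tf_group",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Mann-Whitney tests of each feature, reference group vs each other.

    Groups with fewer than `min_cells` cells are reported as underpowered
    (`tested=False`, no p-value) and excluded from the BH family. BH spans
    the full feature x comparison family; stars mark adjusted p < 0.05 (*)
    and < 0.01 (**). Output ordering (feature-major, canonical group
    order) is deterministic.
    """
    if features is None:
        features = tuple(f for f in DEFAULT_FEATURES if f in table.columns)
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"features missing from table: {missing}")
    if group_col not in table.columns:
        raise ValueError(f"missing group column {group_col!r}")

    by_group = {
        grp: table[table[group_col] == grp]
        for grp in TF_GROUPS
        if (table[group_col] == grp).any()
    }
    if len(by_group) < 2:
        raise ValueError("need at least two non-empty groups")
    if reference not in by_group:
        raise ValueError(f"reference group {reference!r} is empty")
    others = [g for g in TF_GROUPS if g in by_group and g != reference]

    rows = []
    for feat in features:
        ref_vals = by_group[reference][feat].dropna().to_numpy(float)
        for other in others:
            vals = by_group[other][feat].dropna().to_numpy(float)
            tested = len(ref_vals) >= min_cells and len(vals) >= min_cells
            row = {
                "feature": feat,
                "comparison": f"{reference}_vs_{other}",
                "n_ref": len(ref_vals),
                "n_other": len(vals),
                "median_ref": float(np.median(ref_vals)) if len(ref_vals) else np.nan,
                "median_other": float(np.median(vals)) if len(vals) else np.nan,
                "tested": tested,
            }
            if tested:
                u, p = stats.mann_whitney_u(ref_vals, vals)
                row["u_statistic"], row["p_value"] = u, p
            else:
                row["u_statistic"], row["p_value"] = np.nan, np.nan
                log.info(
                    "underpowered comparison %s for %s (n=%d vs %d)",
                    row["comparison"], feat, len(ref_vals), len(vals),
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    tested_mask = out["tested"].to_numpy()
    if tested_mask.any():
        out.loc[tested_mask, "p_adjusted"] = stats.bh_adjust(
            out.loc[tested_mask, "p_value"].to_numpy()
        )
    out["stars"] = [stats.significance_stars(p) for p in out["p_adjusted"]]
    return out
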