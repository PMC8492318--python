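"""Synthetic islet single-cell data with known ground truth.

Generates droplet-style UMI count matrices that emulate the structure of a
dispersed human islet preparation: a multi-donor mixture of ten cell types,
negative-binomial counts with dropout, bimodal on/off transcription-factor
(TF) states in alpha and beta cells coupled to a functional gene program,
ambient contamination shared across droplets, hormone-coexpressing
doublets, and empty droplets. Matched bulk TPM profiles, Patch-Seq-style
electrophysiology tables, and two-channel immunofluorescence intensity
tables are derived from the same ground truth.

Model
-----
* Counts: gene-level means per cell type, multiplied by per-donor lognormal
  batch factors and a per-cell lognormal library-size factor, sampled from
  a negative binomial parameterized by (mean mu, dispersion phi) with
  variance mu + phi * mu^2.
* TF states: each alpha/beta cell draws one of four groups
  (None, A-only, B-only, Both); a TF that is "on" has mean `tf_on_mean`,
  an "off" TF has a small epsilon mean (`tf_off_mean`) so that true absence
  and dropout remain distinguishable. Cells in the Both group have their
  functional program genes scaled by `program_effect`.
* Mitochondrial content: a per-cell fraction drawn from a Beta distribution
  allocated across the MT- genes.
* Ambient RNA: the ambient profile is the library-size-weighted mean of all
  true cells' gene proportions; each droplet swaps a binomial fraction of
  its counts for draws from that profile. Empty droplets carry only ambient
  counts with small totals.
* Doublets: a configured proportion of barcodes are the summed counts of
  two independently generated cells (types drawn from the census).
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
from .matrix import CountMatrix

log = logging.getLogger(__name__)

#: census proportions mirroring a typical dispersed islet preparation
DEFAULT_CENSUS_PROPORTIONS = {
    "alpha": 0.54,
    "beta": 0.24,
    "delta": 0.025,
    "gamma": 0.006,
    "epsilon": 0.002,
    "acinar": 0.033,
    "ductal": 0.047,
    "endothelial": 0.022,
    "stellate": 0.077,
    "immune": 0.008,
}

DEFAULT_TF_ON_FRACTIONS = {
    # (None, A-only, B-only, Both)
    "alpha": (0.10, 0.04, 0.48, 0.38),
    "beta": (0.22, 0.04, 0.52, 0.22),
}


def default_census(total: int = 5000) -> dict[str, int]:
    """Integer per-type cell counts for a target total."""
    counts = {
        ct: max(1, round(p * total)) for ct, p in DEFAULT_CENSUS_PROPORTIONS.items()
    }
    return counts


@dataclass
class SimConfig:
    """Parameters of the synthetic islet dataset."""

    seed: int = 0
    n_cells_per_type: dict[str, int] = field(default_factory=default_census)
    cell_types: tuple[str, ...] = G.CELL_TYPES
    n_genes: int = 600
    marker_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(G.MARKER_MAP)
    )
    tf_pair_per_type: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(G.TF_PAIRS)
    )
    tf_on_fractions: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TF_ON_FRACTIONS)
    )
    program_genes: tuple[str, ...] = G.PROGRAM_GENES
    program_effect: float = 2.0
    nb_dispersion: float = 0.25
    library_size_lognormal: tuple[float, float] = (0.0, 0.3)
    mito_fraction_beta_params: tuple[float, float] = (2.0, 38.0)
    ambient_fraction: float = 0.02
    doublet_rate: float = 0.05
    n_donors: int = 5
    n_empty_droplets: int = 500
    empty_total_range: tuple[int, int] = (10, 80)
    # expression scales (expected counts per cell at library factor 1)
    tf_on_mean: float = 15.0
    tf_off_mean: float = 0.002
    hormone_mean: float = 200.0
    marker_mean: float = 30.0
    program_mean: float = 5.0
    background_mean: float = 1.2
    background_sigma: float = 0.3
    donor_sigma: float = 0.1
    #: fraction of cells given a crippled library (planted QC failures)
    low_quality_rate: float = 0.0

    def required_genes(self) -> list[str]:
        """All named genes, in deterministic order, without duplicates."""
        ordered: list[str] = []
        seen: set[str] = set()
        for ct in self.cell_types:
            for g in self.marker_map.get(ct, ()):
                if g not in seen:
                    ordered.append(g)
                    seen.add(g)
        for pair in self.tf_pair_per_type.values():
            for g in pair:
                if g not in seen:
                    ordered.append(g)
                    seen.add(g)
        for g in self.program_genes:
            if g not in seen:
                ordered.append(g)
                seen.add(g)
        for g in G.MITO_GENES:
            if g not in seen:
                ordered.append(g)
                seen.add(g)
        return ordered

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for name in ("ambient_fraction", "doublet_rate", "low_quality_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for ct, fr in self.tf_on_fractions.items():
            fr = np.asarray(fr, dtype=float)
            if fr.size != 4 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"tf_on_fractions[{ct!r}] must be a 4-vector summing to 1"
                )
        for ct, n in self.n_cells_per_type.items():
            if n < 0:
                raise ValueError(f"negative cell count for {ct!r}")
            if ct not in self.cell_types:
                raise ValueError(f"unknown cell type {ct!r}")
        if self.n_genes < len(self.required_genes()):
            raise ValueError(
                f"n_genes={self.n_genes} smaller than the "
                f"{len(self.required_genes())} named marker/TF/program/MT genes"
            )
        if self.program_effect <= 0:
            raise ValueError("program_effect must be > 0")
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls(**raw)
        # JSON round-trips tuples as lists
        cfg.tf_on_fractions = {k: tuple(v) for k, v in cfg.tf_on_fractions.items()}
        cfg.tf_pair_per_type = {k: tuple(v) for k, v in cfg.tf_pair_per_type.items()}
        cfg.marker_map = {k: tuple(v) for k, v in cfg.marker_map.items()}
        return cfg


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset.

    `cells` has one row per barcode (index = barcode) with columns
    cell_type, tf_group (NaN where the type has no TF pair, and for
    doublets/empties), is_doublet, is_empty, donor, and for doublets the
    `doublet_pair` of constituent types.
    """

    cells: pd.DataFrame
    ambient_profile: pd.Series
    program_genes: tuple[str, ...]
    config: SimConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "truth_cells.tsv", sep="\t")
        self.ambient_profile.rename("ambient_proportion").to_csv(
            outdir / "truth_ambient_profile.tsv", sep="\t"
        )
        self.config.to_json(outdir / "sim_config.json")


def _build_gene_means(cfg: SimConfig, rng: np.random.Generator):
    """Gene list and per-type mean matrix (types x genes).

    TF genes of paired types are left at 0 in the base matrix; they are
    assigned per cell from the drawn TF group. Mitochondrial genes are also
    assigned per cell from the drawn mito fraction.
    """
    named = cfg.required_genes()
    n_bg = cfg.n_genes - len(named)
    symbols = named + [f"BG{i:04d}" for i in range(1, n_bg + 1)]
    gene_ids = [f"SIM{i:07d}" for i in range(1, len(symbols) + 1)]
    col = {s: j for j, s in enumerate(symbols)}

    n_types = len(cfg.cell_types)
    base = np.zeros((n_types, len(symbols)))
    # background expression shared across types, lognormal across genes
    bg_means = rng.lognormal(np.log(cfg.background_mean), cfg.background_sigma,
                             size=len(symbols))
    base[:] = bg_means[None, :]

    tf_cols = {g for pair in cfg.tf_pair_per_type.values() for g in pair}
    mito_cols = [col[g] for g in G.MITO_GENES if g in col]

    for ti, ct in enumerate(cfg.cell_types):
        # markers: strong in own type, epsilon elsewhere
        for other in cfg.cell_types:
            for g in cfg.marker_map.get(other, ()):
                if g not in col:
                    continue
                if other == ct:
                    hi = (
                        cfg.hormone_mean
                        if g == G.HORMONE_GENES.get(ct)
                        else cfg.marker_mean
                    )
                    base[ti, col[g]] = hi
                else:
                    base[ti, col[g]] = cfg.tf_off_mean
        # program genes: moderate in endocrine, low elsewhere
        for g in cfg.program_genes:
            if g in col:
                base[ti, col[g]] = (
                    cfg.program_mean if ct in G.ENDOCRINE_TYPES else 0.3
                )
        # TF genes
        for g in tf_cols:
            if g in col:
                base[ti, col[g]] = cfg.tf_off_mean
        if ct in cfg.tf_pair_per_type:
            for g in cfg.tf_pair_per_type[ct]:
                base[ti, col[g]] = 0.0  # per-cell assignment
        # known off-pair TF biology: ARX detected in gamma/epsilon,
        # MAFB present in immune cells
        if ct in ("gamma", "epsilon") and "ARX" in col:
            base[ti, col["ARX"]] = cfg.tf_on_mean
        if ct == "immune" and "MAFB" in col:
            base[ti, col["MAFB"]] = 3.0
        # mito genes assigned per cell
        for j in mito_cols:
            base[ti, j] = 0.0

    return symbols, gene_ids, col, base, mito_cols


def _sample_counts(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial draws, variance mu + phi*mu^2 (zero where mu=0)."""
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_dataset(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Generate a droplet count matrix and its ground truth.

    Barcode order: singlet cells (grouped by type), then doublets, then
    empty droplets. Identical config (including seed) gives identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    symbols, gene_ids, col, base, mito_cols = _build_gene_means(config, rng)
    n_genes = len(symbols)
    phi = config.nb_dispersion
    type_index = {ct: i for i, ct in enumerate(config.cell_types)}

    # donor batch factors (donor x gene, lognormal around 1)
    donor_factors = rng.lognormal(0.0, config.donor_sigma,
                                  size=(config.n_donors, n_genes))

    # ---- singlets -----------------------------------------------------
    types = [
        ct
        for ct in config.cell_types
        for _ in range(config.n_cells_per_type.get(ct, 0))
    ]
    n_singlets = len(types)
    if n_singlets == 0:
        raise ValueError("no cells requested")

    n_doublets = int(round(config.doublet_rate * n_singlets))
    census_p = np.array(
        [config.n_cells_per_type.get(ct, 0) for ct in config.cell_types], float
    )
    census_p /= census_p.sum()
    doublet_types = [
        (
            config.cell_types[a],
            config.cell_types[b],
        )
        for a, b in zip(
            rng.choice(len(config.cell_types), size=n_doublets, p=census_p),
            rng.choice(len(config.cell_types), size=n_doublets, p=census_p),
        )
    ]

    all_types = types + [t for pair in doublet_types for t in pair]
    n_gen = len(all_types)

    donors = rng.integers(0, config.n_donors, size=n_gen)
    mu_lib, sd_lib = config.library_size_lognormal
    lib = rng.lognormal(mu_lib, sd_lib, size=n_gen)
    lowq = rng.random(n_gen) < config.low_quality_rate
    lib[lowq] *= 0.2

    a_mito, b_mito = config.mito_fraction_beta_params
    mito_frac = rng.beta(a_mito, b_mito, size=n_gen)
    mito_frac[lowq] = np.clip(mito_frac[lowq] + 0.2, 0, 0.9)

    tf_groups = np.full(n_gen, None, dtype=object)
    mu = np.empty((n_gen, n_genes))
    for i, ct in enumerate(all_types):
        m = base[type_index[ct]] * donor_factors[donors[i]]
        if ct in config.tf_pair_per_type:
            grp = rng.choice(4, p=np.asarray(config.tf_on_fractions[ct], float))
            tf_groups[i] = G.TF_GROUPS[grp]
            ga, gb = config.tf_pair_per_type[ct]
            a_on = grp in (1, 3)  # A-only or Both
            b_on = grp in (2, 3)  # B-only or Both
            m = m.copy()
            m[col[ga]] = config.tf_on_mean if a_on else config.tf_off_mean
            m[col[gb]] = config.tf_on_mean if b_on else config.tf_off_mean
            if grp == 3 and config.program_effect != 1.0:
                for g in config.program_genes:
                    if g in col:
                        m[col[g]] = m[col[g]] * config.program_effect
        mu[i] = m * lib[i]
        # mitochondrial load: fraction of the cell's expected total
        nonmt = mu[i].sum()
        mt_total = mito_frac[i] / (1.0 - mito_frac[i]) * nonmt
        if mito_cols:
            mu[i, mito_cols] = mt_total / len(mito_cols)

    counts = _sample_counts(mu, phi, rng)

    # ---- assemble barcodes: singlets + summed doublets ----------------
    singlet_counts = counts[:n_singlets]
    parent_counts = counts[n_singlets:]
    doublet_counts = parent_counts[0::2] + parent_counts[1::2]

    cell_counts = np.vstack([singlet_counts, doublet_counts]) if n_doublets else singlet_counts
    cell_is_doublet = np.r_[
        np.zeros(n_singlets, bool), np.ones(n_doublets, bool)
    ]
    cell_types_out = types + ["doublet"] * n_doublets
    doublet_pairs = [""] * n_singlets + [
        "+".join(sorted(p)) for p in doublet_types
    ]
    cell_donors = np.r_[donors[:n_singlets], donors[n_singlets::2][:n_doublets]]
    cell_tf = np.r_[tf_groups[:n_singlets], np.full(n_doublets, None, object)]

    # ---- ambient profile and contamination ----------------------------
    pooled = counts.sum(axis=0).astype(float)
    if pooled.sum() == 0:
        raise ValueError("degenerate simulation: no counts generated")
    profile = pooled / pooled.sum()

    if config.ambient_fraction > 0:
        removed = rng.binomial(cell_counts, config.ambient_fraction)
        kept = cell_counts - removed
        amb = rng.multinomial(removed.sum(axis=1), profile)
        cell_counts = kept + amb

    # ---- empty droplets ------------------------------------------------
    lo, hi = config.empty_total_range
    if config.n_empty_droplets > 0:
        empty_totals = rng.integers(lo, hi + 1, size=config.n_empty_droplets)
        empty_counts = rng.multinomial(empty_totals, profile)
        full = np.vstack([cell_counts, empty_counts])
    else:
        full = cell_counts

    n_total = full.shape[0]
    barcodes = np.array([f"BC{i:06d}" for i in range(1, n_total + 1)], object)

    cm = CountMatrix(
        sp.csr_matrix(full), barcodes, np.array(gene_ids, object),
        np.array(symbols, object)
    )

    n_empty = n_total - len(cell_types_out)
    truth_df = pd.DataFrame(
        {
            "cell_type": cell_types_out + ["empty"] * n_empty,
            "tf_group": list(cell_tf) + [None] * n_empty,
            "is_doublet": np.r_[cell_is_doublet, np.zeros(n_empty, bool)],
            "is_empty": np.r_[np.zeros(len(cell_types_out), bool),
                              np.ones(n_empty, bool)],
            "donor": [f"donor{d + 1}" for d in cell_donors]
            + [""] * n_empty,
            "doublet_pair": doublet_pairs + [""] * n_empty,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    truth = SimTruth(
        cells=truth_df,
        ambient_profile=pd.Series(profile, index=symbols),
        program_genes=tuple(g for g in config.program_genes if g in col),
        config=config,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# matched bulk profiles
# ---------------------------------------------------------------------------

def generate_bulk(truth: SimTruth, counts: CountMatrix, cell_type: str) -> pd.Series:
    """Bulk TPM profile of one cell type: summed singlet counts per million.

    Deterministic given its inputs (pure aggregation; the 3' UMI chemistry
    makes per-million rescaling the TPM analogue, no length term).
    """
    cells = truth.cells.loc[list(counts.barcodes)]
    mask = (
        (cells["cell_type"] == cell_type)
        & ~cells["is_doublet"]
        & ~cells["is_empty"]
    ).to_numpy()
    if cell_type not in set(cells["cell_type"]) or not mask.any():
        raise ValueError(f"no cells of type {cell_type!r}")
    sums = np.asarray(counts.X[mask].sum(axis=0)).ravel().astype(float)
    tpm = sums / sums.sum() * 1e6
    return pd.Series(tpm, index=counts.gene_symbols, name=f"{cell_type}_TPM")


# ---------------------------------------------------------------------------
# Patch-Seq-style electrophysiology
# ---------------------------------------------------------------------------

#: feature -> baseline mean (units in the name)
EPHYS_FEATURES = {
    "cell_size_pF": 10.0,
    "early_exocytosis_fF_pF": 20.0,
    "late_exocytosis_fF_pF": 15.0,
    "early_ca_current_pA_pF": 12.0,
    "late_ca_current_pA_pF": 8.0,
    "late_ca_conductance_nS_pF": 5.0,
    "na_current_pA_pF": 40.0,
}


def default_ephys_effect_map(noise_sd: float = 1.0) -> dict[str, dict[str, float]]:
    """Both-group shifts emulating enhanced secretory function.

    Exocytosis and Ca2+ parameters shift by +2 noise SD in the Both group;
    cell size is left at the null (equal means across groups).
    """
    shifted = (
        "early_exocytosis_fF_pF",
        "early_ca_current_pA_pF",
        "late_ca_current_pA_pF",
        "late_ca_conductance_nS_pF",
    )
    return {f: {"Both": 2.0 * noise_sd} for f in shifted}


def synthetic_tf_groups(
    n_per_group: int, n_donors: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Minimal truth-like frame with balanced TF groups (for ephys tests)."""
    rng = np.random.default_rng(seed)
    n = n_per_group * len(G.TF_GROUPS)
    return pd.DataFrame(
        {
            "tf_group": np.repeat(G.TF_GROUPS, n_per_group),
            "donor": [f"donor{d + 1}" for d in rng.integers(0, n_donors, n)],
        },
        index=pd.Index([f"PS{i:05d}" for i in range(1, n + 1)], name="cell"),
    )


def generate_ephys(
    truth,
    effect_map: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    cell_type: str = "beta",
) -> pd.DataFrame:
    """Per-cell electrophysiology features with group-specific means.

    Parameters
    ----------
    truth : SimTruth or DataFrame
        Source of per-cell `tf_group` (and `donor`) labels. When a SimTruth
        is given, cells of `cell_type` with a defined TF group are used.
    effect_map : feature -> {group -> additive mean shift}
        Unlisted features/groups shift by 0. All features share `noise_sd`.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(truth, SimTruth):
        cells = truth.cells
        cells = cells[
            (cells["cell_type"] == cell_type) & cells["tf_group"].notna()
        ]
    else:
        cells = truth
    if effect_map is None:
        effect_map = {}
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=cells.index.copy())
    out["tf_group"] = cells["tf_group"].to_numpy()
    out["donor"] = (
        cells["donor"].to_numpy() if "donor" in cells else "donor1"
    )
    n = len(out)
    for feat, base in EPHYS_FEATURES.items():
        shifts = effect_map.get(feat, {})
        mean = np.array([base + shifts.get(g, 0.0) for g in out["tf_group"]])
        out[feat] = mean + rng.normal(0.0, noise_sd, size=n)
    return out


# ---------------------------------------------------------------------------
# two-channel immunofluorescence intensities
# ---------------------------------------------------------------------------

def generate_intensity(
    fractions: tuple[float, float, float, float],
    n_cells: int,
    seed: int = 0,
    n_donors: int = 3,
    lo_params: tuple[float, float] = (2.0, 0.7),
    hi_params: tuple[float, float] = (8.0, 0.9),
) -> pd.DataFrame:
    """Bimodal per-cell marker intensities with planted hi/lo fractions.

    `fractions` follow the (lo/lo, hi/lo, lo/hi, hi/hi) order for the
    (marker_a, marker_b) channels. Intensities are Gaussian around a low or
    high mode; a threshold midway between the modes recovers the planted
    classes up to mode overlap.
    """
    fr = np.asarray(fractions, float)
    if fr.size != 4 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 0.02:
        raise ValueError("fractions must be a 4-vector summing to ~1")
    fr = fr / fr.sum()  # tolerate rounded percentage vectors (e.g. 99%)
    rng = np.random.default_rng(seed)
    grp = rng.choice(4, size=n_cells, p=fr)
    a_hi = np.isin(grp, (1, 3))
    b_hi = np.isin(grp, (2, 3))

    def draw(hi_mask):
        v = rng.normal(lo_params[0], lo_params[1], size=n_cells)
        v_hi = rng.normal(hi_params[0], hi_params[1], size=n_cells)
        return np.where(hi_mask, v_hi, v)

    return pd.DataFrame(
        {
            "donor": [f"donor{d + 1}" for d in rng.integers(0, n_donors, n_cells)],
            "marker_a": draw(a_hi),
            "marker_b": draw(b_hi),
            "true_class": np.array(["lo/lo", "hi/lo", "lo/hi", "hi/hi"])[grp],
        },
        index=pd.Index([f"IF{i:05d}" for i in range(1, n_cells + 1)], name="cell"),
    )
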