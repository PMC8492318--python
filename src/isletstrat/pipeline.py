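"""End-to-end pipeline orchestration, configuration, and run reporting.

`run_pipeline` executes: simulate (optional) -> ambient correction ->
cell/gene QC -> normalization -> hormone-doublet removal -> clustering ->
annotation -> rare-cell relabeling -> TF stratification (per configured
pair) -> dot-plot/group statistics -> bulk/single-cell concordance (when
bulk profiles are available) -> electrophysiology comparison (when a
table is available). Every threshold used is logged to the summary, and
every discarded barcode appears exactly once in the drop ledger with its
reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance as conc
from . import genes as G
from .cluster import ClusterParams, annotate_clusters, embed_and_cluster, select_rare_cells
from .ephys import compare_ephys_groups
from .matrix import CountMatrix
from .qc import QCParams, ambient_correct, filter_cells_genes, mito_fraction, normalize_log, remove_hormone_doublets
from .simulate import SimConfig, default_ephys_effect_map, generate_bulk, generate_dataset, generate_ephys
from .stratify import TFPair, binarize_and_classify, classify_intensity, compare_groups, detected_genes_by_level, dotplot_stats

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RareRule:
    parent_type: str
    gene: str
    new_type: str
    threshold: float = 0.5


def default_tf_pairs() -> list[TFPair]:
    return [
        TFPair("ARX", "MAFB", cell_type="alpha"),
        TFPair("MAFA", "MAFB", cell_type="beta"),
    ]


def default_rare_rules() -> list[RareRule]:
    return [
        RareRule("delta", "PPY", "gamma"),
        RareRule("delta", "GHRL", "epsilon"),
    ]


@dataclass
class PipelineConfig:
    """Single configuration object; every stage block is a named field."""

    seed: int = 0
    outdir: str = "isletstrat_run"
    simulate: SimConfig | None = None
    counts_dir: str | None = None
    metadata_path: str | None = None  # TSV: barcode, donor
    qc: QCParams = field(default_factory=QCParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    run_ambient: bool = True
    tf_pairs: list[TFPair] = field(default_factory=default_tf_pairs)
    rare_rules: list[RareRule] = field(default_factory=default_rare_rules)
    gene_panel: tuple[str, ...] = G.PROGRAM_GENES
    detection: str = "threshold"
    bulk_paths: dict[str, str] = field(default_factory=dict)
    ephys_path: str | None = None
    intensity_path: str | None = None
    intensity_thresholds: tuple[float, float] = (5.0, 5.0)

    def validate(self) -> None:
        self.qc.validate()
        self.cluster.validate()
        if self.simulate is not None:
            self.simulate.validate()
        elif self.counts_dir is None:
            raise ValueError("either simulate or counts_dir must be given")
        if self.detection not in ("threshold", "nonzero"):
            raise ValueError(f"unknown detection mode {self.detection!r}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if raw.get("simulate") is not None:
            sim = SimConfig(**raw["simulate"])
            sim.tf_on_fractions = {
                k: tuple(v) for k, v in sim.tf_on_fractions.items()
            }
            sim.tf_pair_per_type = {
                k: tuple(v) for k, v in sim.tf_pair_per_type.items()
            }
            sim.marker_map = {k: tuple(v) for k, v in sim.marker_map.items()}
            raw["simulate"] = sim
        if "qc" in raw:
            q = dict(raw["qc"])
            if "marker_table" in q:
                q["marker_table"] = pd.DataFrame(q["marker_table"])
            raw["qc"] = QCParams(**q)
        if "cluster" in raw:
            raw["cluster"] = ClusterParams(**raw["cluster"])
        if "tf_pairs" in raw:
            raw["tf_pairs"] = [TFPair(**p) for p in raw["tf_pairs"]]
        if "rare_rules" in raw:
            raw["rare_rules"] = [RareRule(**r) for r in raw["rare_rules"]]
        return cls(**raw)


def _stage(name):
    """Decorator-free stage wrapper used inline below."""
    class _Ctx:
        def __init__(self, n):
            self.name = n

        def __enter__(self):
            log.info("stage: %s", self.name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
            return False

    return _Ctx(name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; write tables + summary.json to outdir.

    Returns the summary dict. Partial outputs written before a failing
    stage are retained on disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "thresholds": _threshold_report(config)}
    truth = None

    with _stage("simulate" if config.simulate is not None else "load"):
        if config.simulate is not None:
            raw, truth = generate_dataset(config.simulate)
            truth.write(outdir)
            donors = truth.cells["donor"]
        else:
            raw = CountMatrix.read_10x(config.counts_dir)
            if config.metadata_path:
                meta = pd.read_csv(
                    config.metadata_path, sep="\t", index_col=0
                )
                donors = meta["donor"].reindex(raw.barcodes).fillna("donor1")
            else:
                donors = pd.Series("donor1", index=raw.barcodes)
    summary["n_input_barcodes"] = int(raw.n_cells)

    ledger: dict[str, str] = {}

    with _stage("ambient_correct"):
        if config.run_ambient:
            amb = ambient_correct(raw, config.qc)
            cells_raw = amb.cells
            for bc in amb.empty_barcodes:
                ledger[bc] = "empty"
            summary["n_empty"] = int(len(amb.empty_barcodes))
            summary["n_ambient_genes"] = len(amb.ambient_genes)
            pd.Series(amb.ambient_genes, name="gene").to_csv(
                outdir / "ambient_genes.tsv", sep="\t", index=False
            )
        else:
            cells_raw = raw
            summary["n_empty"] = 0
            summary["n_ambient_genes"] = 0

    with _stage("filter_cells_genes"):
        filtered, qc_table = filter_cells_genes(cells_raw, config.qc)
        qc_table.to_csv(outdir / "qc_table.tsv", sep="\t")
        dropped = qc_table[~qc_table["keep"]]
        for bc, row in dropped.iterrows():
            ledger[bc] = f"qc:{row['drop_reason']}"
        summary["n_qc_dropped"] = int(len(dropped))
        summary["qc_drop_reasons"] = (
            dropped["drop_reason"].value_counts().to_dict()
        )

    with _stage("normalize_log"):
        norm = normalize_log(filtered, config.qc.size_factor)

    with _stage("remove_hormone_doublets"):
        keep, drops = remove_hormone_doublets(norm, config.qc)
        for bc, row in drops.iterrows():
            ledger[bc] = f"doublet:{row['rule']}"
        summary["n_doublet_dropped"] = int(len(drops))
        summary["doublet_rules"] = drops["rule"].value_counts().to_dict()
        norm = norm.subset_cells(np.flatnonzero(keep))
        filtered = filtered.subset_cells(np.flatnonzero(keep))

    summary["n_retained"] = int(norm.n_cells)
    for bc in norm.barcodes:
        ledger[bc] = "retained"
    ledger_df = pd.DataFrame(
        {"disposition": [ledger[bc] for bc in raw.barcodes]},
        index=pd.Index(raw.barcodes, name="barcode"),
    )
    ledger_df.to_csv(outdir / "drop_ledger.tsv", sep="\t")

    with _stage("embed_and_cluster"):
        covariates = pd.DataFrame(
            {"mito_fraction": mito_fraction(filtered, config.qc.mito_regex)}
        )
        clusters, _ = embed_and_cluster(
            norm, config.cluster, seed=config.seed, covariates=covariates
        )
        summary["n_clusters"] = int(clusters.max() + 1)

    with _stage("annotate_clusters"):
        mapping = annotate_clusters(clusters, norm, config.qc.marker_table)
        cell_table = pd.DataFrame(
            {
                "cluster": clusters,
                "cell_type": [mapping[int(c)] for c in clusters],
                "donor": donors.reindex(norm.barcodes).to_numpy(),
            },
            index=pd.Index(norm.barcodes, name="barcode"),
        )
        summary["cluster_annotation"] = {str(k): v for k, v in mapping.items()}

    with _stage("select_rare_cells"):
        for rule in config.rare_rules:
            if norm.has_gene(rule.gene) and (
                cell_table["cell_type"] == rule.parent_type
            ).any():
                cell_table = select_rare_cells(
                    cell_table, norm, rule.gene, rule.threshold,
                    rule.parent_type, rule.new_type,
                )
        cell_table.to_csv(outdir / "cell_table.tsv", sep="\t")
        summary["cell_type_counts"] = (
            cell_table["cell_type"].value_counts().to_dict()
        )

    summary["tf_fractions"] = {}
    summary["per_donor_fractions"] = {}
    with _stage("tf_stratify"):
        for pair in config.tf_pairs:
            if not (cell_table["cell_type"] == pair.cell_type).any():
                log.warning("no %s cells; skipping pair %s/%s",
                            pair.cell_type, pair.gene_a, pair.gene_b)
                continue
            res = binarize_and_classify(norm, cell_table, pair,
                                        detection=config.detection)
            ct = pair.cell_type
            cell_table.loc[res.labels.index, "tf_group"] = res.labels
            summary["tf_fractions"][ct] = {
                k: float(v) for k, v in res.pooled_fractions.items()
            }
            summary["per_donor_fractions"][ct] = {
                d: {k: float(v) for k, v in row.items()}
                for d, row in res.per_donor_fractions.iterrows()
            }
            res.per_donor_fractions.to_csv(
                outdir / f"fractions_{ct}.tsv", sep="\t"
            )
            panel = [g for g in config.gene_panel]
            dot = dotplot_stats(norm, res, panel)
            dot.to_csv(outdir / f"dotplot_{ct}.tsv", sep="\t", index=False)
            tests = compare_groups(norm, res, panel)
            tests.to_csv(outdir / f"group_tests_{ct}.tsv", sep="\t",
                         index=False)
            dg = detected_genes_by_level(
                norm, pair.gene_b, pair.threshold,
                cell_mask=np.isin(norm.barcodes, res.labels.index.to_numpy()),
            )
            dg.to_csv(outdir / f"detected_genes_{ct}.tsv", sep="\t")
        cell_table.to_csv(outdir / "cell_table.tsv", sep="\t")

    with _stage("concordance"):
        bulk = {}
        if truth is not None:
            for ct in ("alpha", "beta"):
                try:
                    bulk[ct] = generate_bulk(truth, raw, ct)
                except ValueError:
                    pass
        for ct, path in config.bulk_paths.items():
            bulk[ct] = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]
        if bulk:
            summary["concordance"] = {}
            for ct, profile in bulk.items():
                if not (cell_table["cell_type"] == ct).any():
                    continue
                pseudo = conc.pseudobulk(filtered, cell_table, ct)
                try:
                    cres = conc.expression_concordance(profile, pseudo)
                    summary["concordance"][ct] = {
                        "r": cres.r, "n_genes": cres.n_genes,
                    }
                except ValueError as e:
                    summary["concordance"][ct] = {"error": str(e)}
            if (
                "alpha" in bulk
                and "beta" in bulk
                and (cell_table["cell_type"] == "alpha").any()
                and (cell_table["cell_type"] == "beta").any()
            ):
                types = cell_table["cell_type"].reindex(norm.barcodes)
                mask_a = (types == "alpha").to_numpy()
                mask_b = (types == "beta").to_numpy()
                de = conc.de_and_fc_concordance(
                    bulk["alpha"], bulk["beta"], filtered, norm,
                    mask_a, mask_b,
                )
                de.bulk.to_csv(outdir / "bulk_de.tsv", sep="\t")
                de.sc.to_csv(outdir / "sc_de.tsv", sep="\t")
                summary["de_concordance"] = {
                    "fc_correlation": de.fc_correlation,
                    "n_joint_significant": de.n_joint_significant,
                    "n_discordant": de.n_discordant,
                }

    with _stage("ephys"):
        etab = None
        if config.ephys_path:
            etab = pd.read_csv(config.ephys_path, index_col=0)
        elif truth is not None and (
            truth.cells["tf_group"].notna() & (truth.cells["cell_type"] == "beta")
        ).sum() >= 8:
            etab = generate_ephys(
                truth, default_ephys_effect_map(), seed=config.seed
            )
        if etab is not None:
            etests = compare_ephys_groups(etab)
            etests.to_csv(outdir / "ephys_tests.tsv", sep="\t", index=False)
            summary["ephys_significant"] = sorted(
                etests.loc[
                    etests["p_adjusted"].notna()
                    & (etests["p_adjusted"] < 0.05),
                    "feature",
                ].unique().tolist()
            )

    with _stage("intensity"):
        if config.intensity_path:
            itab = pd.read_csv(config.intensity_path, index_col=0)
            ires = classify_intensity(itab, config.intensity_thresholds)
            summary["intensity_fractions"] = {
                k: float(v) for k, v in ires.pooled_fractions.items()
            }

    # ledger identity check
    counts_by_kind = {
        "retained": summary["n_retained"],
        "empty": summary["n_empty"],
        "qc": summary["n_qc_dropped"],
        "doublet": summary["n_doublet_dropped"],
    }
    assert sum(counts_by_kind.values()) == summary["n_input_barcodes"], (
        "drop ledger does not account for every barcode"
    )
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonable)
    )
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _threshold_report(config: PipelineConfig) -> dict:
    q = config.qc
    return {
        "min_genes": q.min_genes,
        "max_genes": q.max_genes,
        "max_mito_fraction": q.max_mito_fraction,
        "min_cells_per_gene": q.min_cells_per_gene,
        "size_factor": q.size_factor,
        "ins_doublet_threshold": q.ins_doublet_threshold,
        "gcg_doublet_threshold": q.gcg_doublet_threshold,
        "positive_level": q.positive_level,
        "ambient_umi_cutoff": q.ambient_umi_cutoff,
        "ambient_prominence": q.ambient_prominence,
        "n_hvg": config.cluster.n_hvg,
        "n_pcs": config.cluster.n_pcs,
        "resolution": config.cluster.resolution,
        "knn_k": config.cluster.knn_k,
        "tf_pairs": [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "cell_type": p.cell_type,
                "threshold": p.threshold,
            }
            for p in config.tf_pairs
        ],
        "detection": config.detection,
    }
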