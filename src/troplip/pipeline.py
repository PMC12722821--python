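"""End-to-end orchestration: simulate → summarize → DE → GSEA → overlap
graph → pathway OR → DEG overlap → TF activity, from one config mapping.

Every stage writes TSV outputs into the run directory and registers them in
a JSON manifest with SHA-256 hashes, so reruns with the same config and
seed can be checked for bitwise identity.  All randomness flows from the
single top-level seed, expanded deterministically per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import pandas as pd

from . import diffexp, direction_enrichment, enrichment, expression_stats
from . import simdata, tf_activity
from .errors import ConfigError, TroplipError
from .io_formats import (
    read_bulk,
    read_gmt,
    read_regulons,
    read_single_cell,
    write_bulk,
    write_gmt,
    write_regulons,
    write_single_cell,
    write_table,
)

log = logging.getLogger("troplip")

DEFAULT_THRESHOLDS = {"lfc": 0.6, "fdr": 0.05, "base_mean": 1.0}
DEFAULT_GSEA = {"n_perm": 1000, "min_size": 5, "max_size": 500}


def _stage_seed(seed: int, stage: str) -> int:
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def sim_config_from_mapping(mapping: dict, seed: int) -> simdata.SimConfig:
    """Build a :class:`simdata.SimConfig` from a plain config mapping."""
    mapping = dict(mapping or {})
    spikes = [
        simdata.SpikeSpec(
            label=s["label"], size=int(s["size"]),
            log2fc=float(s["log2fc"]),
            clusters=tuple(s.get("clusters", ())),
        )
        for s in mapping.pop("spike_table", [])
    ]
    regs = [
        simdata.RegulonSpec(
            tf=r["tf"], n_targets=int(r["n_targets"]),
            activation_frac=float(r.get("activation_frac", 1.0)),
            unknown_frac=float(r.get("unknown_frac", 0.0)),
            responsive_frac=float(r.get("responsive_frac", 0.8)),
            log2fc=float(r.get("log2fc", 2.0)),
            active=bool(r.get("active", True)),
        )
        for r in mapping.pop("regulon_spec", [])
    ]
    mapping.pop("seed", None)
    if "clusters" in mapping:
        mapping["clusters"] = {
            k: {c: int(n) for c, n in v.items()}
            for k, v in mapping["clusters"].items()
        }
    if "conditions" in mapping:
        mapping["conditions"] = tuple(mapping["conditions"])
    try:
        return simdata.SimConfig(
            spike_table=spikes, regulon_spec=regs, seed=seed, **mapping
        )
    except TypeError as exc:
        raise ConfigError(f"unknown simulation option: {exc}")


def default_sim_mapping() -> dict:
    """The bundled study-shaped simulation: one down-spiked 19-gene
    cholesterol-biosynthesis-like set in SCT-like cells plus bulk, an
    up-spiked hypoxia-response-like set everywhere, and one active TF."""
    return {
        "n_genes": 800,
        "clusters": {
            "VCT": {"Ctrl": 400, "PE": 400},
            "SCT": {"Ctrl": 500, "PE": 500},
            "EVT": {"Ctrl": 250, "PE": 250},
        },
        "spike_table": [
            {"label": "CHOL_BIOSYNTH", "size": 19, "log2fc": -1.0,
             "clusters": ["SCT"]},
            {"label": "HYPOXIA_UP", "size": 30, "log2fc": 1.0},
        ],
        "regulon_spec": [
            {"tf": "TF_HIF_LIKE", "n_targets": 12, "activation_frac": 0.75,
             "responsive_frac": 0.8, "log2fc": 2.0, "active": True},
            {"tf": "TF_NULL", "n_targets": 12, "activation_frac": 0.75,
             "active": False},
        ],
    }


class PipelineRun:
    """One configured run; stages append to the manifest as they finish."""

    def __init__(self, config: dict):
        self.config = dict(config)
        self.seed = int(self.config.get("seed", 0))
        self.outdir = Path(self.config.get("outdir", "troplip_run"))
        contrast = self.config.get("contrast", {})
        self.case = contrast.get("case", "PE")
        self.control = contrast.get("control", "Ctrl")
        self.thresholds = {**DEFAULT_THRESHOLDS,
                           **self.config.get("thresholds", {})}
        self.gsea_opts = {**DEFAULT_GSEA, **self.config.get("gsea", {})}
        self.overlap_threshold = float(self.config.get("overlap_threshold", 25))
        self.manifest = {"seed": self.seed, "stages": []}
        self.outdir.mkdir(parents=True, exist_ok=True)

    # -- bookkeeping -------------------------------------------------------
    def _record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        entry = {
            "stage": stage,
            "params": params,
            "outputs": {
                str(p.relative_to(self.outdir)):
                    hashlib.sha256(p.read_bytes()).hexdigest()
                for p in outputs
            },
            "status": "ok",
        }
        self.manifest["stages"].append(entry)
        log.info("stage %s finished (%d outputs)", stage, len(outputs))

    def _write(self, df: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = self.outdir / name
        write_table(df, path, index=index)
        return path

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> None:
        mapping = self.config.get("simulate") or default_sim_mapping()
        sim_seed = _stage_seed(self.seed, "simulate")
        cfg = sim_config_from_mapping(mapping, sim_seed)
        self.sim_config = cfg
        cells, self.sc_truth = simdata.simulate_single_cell_dataset(cfg)
        bulk, self.bulk_truth = simdata.simulate_bulk_dataset(cfg)
        catalog = simdata.make_gene_set_catalog(cfg)
        regulons = simdata.make_regulon_table(cfg)

        d = self.outdir
        write_single_cell(cells, d / "matrix.mtx", d / "genes.tsv",
                          d / "cells.tsv")
        write_bulk(bulk, d / "bulk_counts.tsv", d / "bulk_samples.tsv",
                   d / "gene_lengths.tsv")
        write_gmt(catalog, d / "sets.gmt")
        write_regulons(regulons, d / "regulons.tsv")
        self.cells, self.bulk = cells, bulk
        self.catalog, self.regulons = catalog, regulons
        self._record("simulate", {"seed": sim_seed}, [
            d / "matrix.mtx", d / "genes.tsv", d / "cells.tsv",
            d / "bulk_counts.tsv", d / "bulk_samples.tsv",
            d / "gene_lengths.tsv", d / "sets.gmt", d / "regulons.tsv",
        ])

    def stage_load(self) -> None:
        inputs = self.config["inputs"]
        self.cells = read_single_cell(
            inputs["matrix"], inputs["genes"], inputs["cells"]
        )
        self.bulk = read_bulk(
            inputs["bulk_counts"], inputs["bulk_samples"],
            inputs["gene_lengths"],
        )
        self.catalog = read_gmt(inputs["sets"])
        self.regulons = read_regulons(inputs["regulons"])
        self.sc_truth = self.bulk_truth = None
        self._record("load", {k: str(v) for k, v in inputs.items()}, [])

    def stage_summarize(self) -> None:
        self.cpm = expression_stats.compute_cpm(self.cells)
        summary = expression_stats.summarize_cluster_groups(
            self.cells, self.cpm
        )
        self.summary = summary
        dot = expression_stats.dotplot_log2fc(summary, self.case, self.control)
        self.dotplot = dot
        panel = sorted({g for _, members in self.catalog for g in members})
        anova = expression_stats.high_expressor_anova_table(
            self.cells, self.cpm, genes=panel
        )
        outs = [
            self._write(summary.table, "summary.tsv"),
            self._write(dot.log2fc, "dotplot_log2fc.tsv", index=True),
            self._write(dot.control_p95, "dotplot_control_p95.tsv", index=True),
            self._write(anova, "high_expressor_anova.tsv"),
        ]
        self._record("summarize", {"case": self.case, "control": self.control},
                     outs)

    def stage_de(self) -> None:
        outs = []
        self.cluster_de = {}
        self.cluster_ranked = {}
        self.mwu_de = {}
        pb = diffexp.aggregate_pseudobulk(self.cells)
        outs.append(self._write(pb.counts, "pseudobulk_counts.tsv", index=True))
        for cluster in sorted(self.cells.cell_meta["cluster"].unique()):
            de, ranked = diffexp.pseudobulk_de(
                pb, cluster, self.case, self.control
            )
            self.cluster_de[cluster] = de
            self.cluster_ranked[cluster] = ranked
            outs.append(self._write(de, f"de_pseudobulk_{cluster}.tsv",
                                    index=True))
            outs.append(self._write(ranked, f"ranked_{cluster}.tsv"))
            mwu = diffexp.mannwhitney_de(
                self.cells, self.cpm, cluster, self.case, self.control
            )
            self.mwu_de[cluster] = mwu
            outs.append(self._write(mwu, f"de_cells_{cluster}.tsv", index=True))

        factors = diffexp.tmm_factors(self.bulk.counts)
        fpkm = diffexp.compute_fpkm(self.bulk, factors)
        kept = diffexp.filter_low_expressed(
            fpkm, self.bulk.sample_meta["condition"]
        )
        de, ranked = diffexp.fit_nb_wald_de(
            self.bulk.counts.loc[kept],
            self.bulk.sample_meta.set_index("sample_id")["condition"],
            self.case, self.control,
        )
        self.bulk_de, self.bulk_ranked = de, ranked
        outs.append(self._write(
            factors.rename_axis("sample_id").reset_index(), "tmm_factors.tsv"
        ))
        outs.append(self._write(de, "de_bulk.tsv", index=True))
        outs.append(self._write(ranked, "ranked_bulk.tsv"))
        self._record("de", {"case": self.case, "control": self.control,
                            "n_genes_bulk_kept": int(len(kept))}, outs)

    def stage_gsea(self) -> None:
        opts = self.gsea_opts
        seed = _stage_seed(self.seed, "gsea")
        result = enrichment.preranked_gsea(
            self.bulk_ranked, self.catalog,
            n_perm=int(opts["n_perm"]), seed=seed,
            min_size=int(opts["min_size"]), max_size=int(opts["max_size"]),
        )
        self.gsea_bulk = result
        tab = result.table.copy()
        tab["leading_edge"] = [
            ",".join(result.leading_edges[s]) for s in tab["set"]
        ]
        outs = [self._write(tab, "gsea_bulk.tsv")]
        self._record("gsea", {"n_perm": opts["n_perm"], "seed": seed}, outs)

    def stage_overlap_graph(self) -> None:
        outs = []
        for direction in ("up", "down"):
            graph = enrichment.build_overlap_graph(
                self.gsea_bulk, direction=direction,
                weight_threshold=self.overlap_threshold,
                fdr_threshold=self.thresholds["fdr"],
            )
            outs.append(self._write(graph.edges, f"overlap_edges_{direction}.tsv"))
            outs.append(self._write(graph.clusters,
                                    f"overlap_clusters_{direction}.tsv"))
        self._record("overlap-graph",
                     {"threshold": self.overlap_threshold}, outs)

    def stage_pathway_or(self) -> None:
        outs = []
        self.pathway_or = {}
        for cluster, mwu in self.mwu_de.items():
            res = direction_enrichment.pathway_direction_tests(
                self.catalog, mwu, direction="down"
            )
            self.pathway_or[cluster] = res
            outs.append(self._write(res, f"pathway_or_down_{cluster}.tsv"))
        bulk_res = direction_enrichment.pathway_direction_tests(
            self.catalog, self.bulk_de.dropna(subset=["log2fc"]),
            direction="down",
        )
        self.pathway_or["bulk"] = bulk_res
        outs.append(self._write(bulk_res, "pathway_or_down_bulk.tsv"))
        self._record("pathway-or", {"direction": "down"}, outs)

    def stage_deg_overlap(self) -> None:
        bulk_degs = set(
            self.bulk_de.index[self.bulk_de["direction"] != "ns"]
        )
        pairs = {}
        for cluster, de in self.cluster_de.items():
            shared = self.bulk_de.index.intersection(de.index)
            degs = set(de.loc[shared].index[
                de.loc[shared, "direction"] != "ns"
            ])
            pairs[f"bulk_vs_{cluster}"] = (
                sorted(bulk_degs & set(shared)), sorted(degs)
            )
        universe = sorted(self.bulk_de.index)
        res = direction_enrichment.deg_overlap_tests(pairs, universe)
        self.deg_overlap = res
        outs = [self._write(res, "deg_overlap.tsv")]
        self._record("deg-overlap", {}, outs)

    def stage_tf_activity(self) -> None:
        labels = tf_activity.classify_deg_direction(
            self.bulk_de.dropna(subset=["padj"]),
            lfc_threshold=self.thresholds["lfc"],
            fdr_threshold=self.thresholds["fdr"],
        )
        res = tf_activity.score_tf_activity(labels, self.regulons)
        self.tf_result = res
        outs = [self._write(res, "tf_activity.tsv")]
        groups = tf_activity.summarize_tf_groups(res)
        for verdict, tab in groups.items():
            outs.append(self._write(tab, f"tf_{verdict}.tsv"))
        self._record("tf-activity", dict(self.thresholds), outs)

    # -- driver ------------------------------------------------------------
    def run_all(self) -> dict:
        t0 = time.time()
        if "inputs" in self.config:
            self.stage_load()
        else:
            self.stage_simulate()
        for stage in (
            self.stage_summarize, self.stage_de, self.stage_gsea,
            self.stage_overlap_graph, self.stage_pathway_or,
            self.stage_deg_overlap, self.stage_tf_activity,
        ):
            stage()
        self.manifest["wall_seconds"] = round(time.time() - t0, 2)
        manifest_path = self.outdir / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2,
                                            sort_keys=True))
        return self.manifest


def run_all(config: dict) -> dict:
    """Validate the config and execute every stage; returns the manifest."""
    contrast = config.get("contrast", {})
    case = contrast.get("case", "PE")
    control = contrast.get("control", "Ctrl")
    if case == control:
        raise ConfigError("contrast case and control must differ")
    if "simulate" in config and config["simulate"]:
        # fail early on unknown clusters/conditions before any stage runs
        sim_config_from_mapping(config["simulate"], 0).validate()
        conds = config["simulate"].get("conditions", ("Ctrl", "PE"))
        if case not in conds or control not in conds:
            raise ConfigError(
                f"contrast ({case!r}, {control!r}) not among simulated "
                f"conditions {tuple(conds)}"
            )
    for key, value in config.get("thresholds", {}).items():
        if value <= 0:
            raise ConfigError(f"threshold {key!r} must be positive")
    return PipelineRun(config).run_all()
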