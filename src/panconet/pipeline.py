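"""End-to-end pipeline driver.

Stages run in order — preprocess, network (threshold + planar graph +
multiscale modules + hubs), enrichment, prognosis, epigenomics, chromatin,
preservation, aggregation — each writing its tables under the output
directory, with a run manifest recording versions, seeds, thresholds, and
per-stage counts. Stages read their inputs from the upstream stage's files,
so any stage can be rerun from cached outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from . import chromatin as chrom_mod
from . import enrichment as enr_mod
from . import epigenomics as epi_mod
from . import io as pio
from . import network as net_mod
from . import preservation as pres_mod
from . import prognosis as prog_mod
from .config import PipelineConfig
from .preprocess import preprocess as _preprocess

logger = logging.getLogger("panconet")

STAGES = ["preprocess", "network", "enrichment", "prognosis", "epigenomics",
          "chromatin", "preservation"]


def _cohort_labels(input_dir: Path) -> list[str]:
    labels = sorted(p.name[:-len(".expr.tsv")]
                    for p in input_dir.glob("*.expr.tsv"))
    if not labels:
        raise FileNotFoundError(f"no *.expr.tsv cohort matrices in "
                                f"{input_dir}")
    return labels


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path.name}: rerun stage "
            f"'{stage}' first")
    return path


def _read_module_table(path: Path) -> net_mod.ModuleHierarchy:
    df = pd.read_csv(path, sep="\t", dtype={"module_id": str,
                                            "parent_id": str})
    modules = []
    for row in df.itertuples(index=False):
        parent = None if row.parent_id == "root" else row.parent_id
        q = None if pd.isna(row.q) else float(row.q)
        modules.append(net_mod.Module(row.module_id,
                                      frozenset(row.genes.split(",")),
                                      parent, int(row.depth), q))
    return net_mod.ModuleHierarchy(modules)


class Pipeline:
    """Stage-wise runner over a fixture directory of per-cohort files."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.input_dir = Path(config.input_dir)
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.cohorts = _cohort_labels(self.input_dir)
        self.manifest: dict = {"version": __version__, "seed": config.seed,
                               "cohorts": self.cohorts, "stages": {},
                               "thresholds": {
                                   "corr_fdr_alpha": config.corr_fdr_alpha,
                                   "module_size": [config.min_module_size,
                                                   config.max_module_size],
                                   "min_overlap": config.min_overlap,
                                   "fc_threshold": config.fc_threshold,
                                   "delta_beta": config.delta_beta_threshold,
                                   "maf": config.maf_cutoff,
                                   "promoter": [config.promoter_upstream,
                                                config.promoter_downstream],
                                   "jaccard": [config.jaccard_specific,
                                               config.jaccard_conserved],
                                   "min_aggregation_weight":
                                       config.min_aggregation_weight,
                                   "cox_alpha": config.cox_alpha}}

    # ------------------------------------------------------------ helpers

    def _samples(self, label: str) -> pd.DataFrame:
        return pio.read_clinical(
            _require(self.input_dir / f"{label}.samples.tsv", "simulate"))

    def _tumor_covariates(self, label: str,
                          expr_cols) -> tuple[pd.Series, pd.DataFrame]:
        samples = self._samples(label)
        groups = samples["group"] if "group" in samples.columns else \
            pd.Series("tumor", index=samples.index)
        cov_cols = [c for c in self.cfg.covariates if c in samples.columns]
        return groups.reindex(expr_cols), samples.loc[:, cov_cols]

    def _write_manifest(self) -> None:
        pio.write_json(self.manifest, self.out / "manifest.json")

    # ------------------------------------------------------------- stages

    def run_preprocess(self) -> None:
        for label in self.cohorts:
            raw = pio.read_expression(self.input_dir / f"{label}.expr.tsv")
            groups, cov = self._tumor_covariates(label, raw.columns)
            tumor = raw.columns[(groups == "tumor").to_numpy()]
            adj = _preprocess(
                raw[tumor], cov.reindex(tumor),
                max_bad_fraction=self.cfg.max_bad_fraction,
                apply_log2=self.cfg.apply_log2,
                log2_offset=self.cfg.log2_offset)
            pio.write_expression(adj, self.out / f"{label}.adjusted.tsv")
            self.manifest["stages"].setdefault("preprocess", {})[label] = {
                "genes_in": int(raw.shape[0]), "genes_kept": int(adj.shape[0]),
                "tumor_samples": int(adj.shape[1])}
        self._write_manifest()

    def run_network(self) -> None:
        for label in self.cohorts:
            expr = pio.read_expression(
                _require(self.out / f"{label}.adjusted.tsv", "preprocess"))
            thr = net_mod.permutation_fdr_threshold(
                expr, n_perm=self.cfg.n_corr_permutations,
                alpha=self.cfg.corr_fdr_alpha, seed=self.cfg.seed,
                grid_step=self.cfg.corr_grid_step)
            net = net_mod.build_pfn(thr.pairs)
            edges = pd.DataFrame(
                [{"gene_a": min(u, v), "gene_b": max(u, v),
                  "abs_r": d["weight"], "r": d["r"]}
                 for u, v, d in net.edges(data=True)])
            if len(edges):
                edges = edges.sort_values(
                    ["abs_r", "gene_a", "gene_b"],
                    ascending=[False, True, True]).reset_index(drop=True)
            edges.to_csv(self.out / f"{label}.edges.tsv", sep="\t",
                         index=False)
            hierarchy = net_mod.multiscale_cluster(
                net, min_size=self.cfg.min_module_size,
                max_size=self.cfg.max_module_size, seed=self.cfg.seed)
            hierarchy.to_frame().to_csv(self.out / f"{label}.modules.tsv",
                                        sep="\t", index=False)
            hubs = net_mod.detect_hubs(net, n_perm=self.cfg.hub_permutations,
                                       alpha=self.cfg.hub_alpha,
                                       seed=self.cfg.seed)
            net_mod.hubs_to_frame(hubs).to_csv(
                self.out / f"{label}.hubs.tsv", sep="\t", index=False)
            self.manifest["stages"].setdefault("network", {})[label] = {
                "cutoff": thr.chosen_cutoff,
                "significant_pairs": int(len(thr.pairs)),
                "edges": int(net.number_of_edges()),
                "modules": len(hierarchy.modules),
                "hubs": sum(h.is_hub for h in hubs)}
        self._write_manifest()

    def run_enrichment(self) -> None:
        gene_annot = pio.read_gene_annotation(
            _require(self.input_dir / "genes.tsv", "simulate"))
        gmt_path = self.input_dir / "planted_modules.gmt"
        for label in self.cohorts:
            hierarchy = _read_module_table(
                _require(self.out / f"{label}.modules.tsv", "network"))
            universe = set(next(m for m in hierarchy.modules
                                if m.parent is None).genes)
            bands = enr_mod.cytoband_enrichment(
                hierarchy, gene_annot, universe,
                (self.cfg.min_module_size, self.cfg.max_module_size),
                self.cfg.min_overlap, self.cfg.enrichment_alpha)
            bands.to_csv(self.out / f"{label}.cytoband_enrichment.tsv",
                         sep="\t", index=False)
            n_sig = int(bands["significant"].sum()) if len(bands) else 0
            stage = self.manifest["stages"].setdefault("enrichment", {})
            stage[label] = {"cytoband_tests": int(len(bands)),
                            "significant": n_sig}
            if gmt_path.exists():
                coll = enr_mod.GeneSetCollection(
                    "gmt", pio.read_gmt(gmt_path), universe)
                res = enr_mod.enrich_hierarchy(
                    hierarchy, coll,
                    (self.cfg.min_module_size, self.cfg.max_module_size),
                    self.cfg.min_overlap, self.cfg.enrichment_alpha)
                res.to_csv(self.out / f"{label}.gmt_enrichment.tsv",
                           sep="\t", index=False)
        self._write_manifest()

    def run_prognosis(self) -> None:
        for label in self.cohorts:
            expr = pio.read_expression(
                _require(self.out / f"{label}.adjusted.tsv", "preprocess"))
            hierarchy = _read_module_table(
                _require(self.out / f"{label}.modules.tsv", "network"))
            clin = pio.read_clinical(
                _require(self.input_dir / f"{label}.clinical.tsv",
                         "simulate"))
            results = []
            for mod in hierarchy.eligible(self.cfg.min_module_size,
                                          self.cfg.max_module_size):
                if mod.parent is None:
                    continue
                try:
                    eig = prog_mod.compute_eigengene(set(mod.genes), expr,
                                                     mod.id)
                    if self.cfg.cox_mode == "continuous":
                        res = prog_mod.cox_fit_continuous(eig.scores, clin,
                                                          mod.id)
                    else:
                        groups = prog_mod.median_stratify(eig.scores)
                        res = prog_mod.cox_fit(groups, clin, mod.id)
                except ValueError as e:
                    logger.warning("prognosis %s %s skipped: %s", label,
                                   mod.id, e)
                    continue
                res.prognostic = bool(np.isfinite(res.p)
                                      and res.p < self.cfg.cox_alpha)
                results.append(res)
            frame = prog_mod.cox_results_to_frame(results)
            frame.to_csv(self.out / f"{label}.prognosis.tsv", sep="\t",
                         index=False)
            self.manifest["stages"].setdefault("prognosis", {})[label] = {
                "modules_tested": len(results),
                "prognostic": int(frame["prognostic"].sum())
                if len(frame) else 0}
        self._write_manifest()

    def run_epigenomics(self) -> None:
        gene_annot = pio.read_gene_annotation(
            _require(self.input_dir / "genes.tsv", "simulate"))
        for label in self.cohorts:
            raw = pio.read_expression(self.input_dir / f"{label}.expr.tsv")
            groups, cov = self._tumor_covariates(label, raw.columns)
            if groups.nunique() < 2:
                logger.info("epigenomics %s: no normal samples; skipped",
                            label)
                continue
            cov_use = cov.reindex(raw.columns)
            deg_raw = epi_mod.moderated_t_test(raw, groups, cov_use)
            degs = epi_mod.call_degs(deg_raw, self.cfg.fc_threshold,
                                     self.cfg.deg_alpha)
            degs.to_csv(self.out / f"{label}.degs.tsv", sep="\t",
                        index_label="gene")
            beta = pio.read_beta(
                _require(self.input_dir / f"{label}.beta.tsv", "simulate"))
            probe_annot = pio.read_probe_annotation(
                _require(self.input_dir / f"{label}.probes.tsv", "simulate"))
            dmc_raw = epi_mod.moderated_t_test(
                beta, groups.reindex(beta.columns),
                cov.reindex(beta.columns))
            dmcs = epi_mod.call_dmcs(dmc_raw, probe_annot,
                                     self.cfg.delta_beta_threshold,
                                     self.cfg.dmc_alpha, self.cfg.maf_cutoff)
            dmcs.to_csv(self.out / f"{label}.dmcs.tsv", sep="\t",
                        index_label="probe")
            mapping = epi_mod.map_promoter_probes(
                probe_annot, gene_annot, self.cfg.promoter_upstream,
                self.cfg.promoter_downstream)
            mapping.to_csv(self.out / f"{label}.promoter_probes.tsv",
                           sep="\t", index=False)
            hierarchy = _read_module_table(
                _require(self.out / f"{label}.modules.tsv", "network"))
            universe = set(next(m for m in hierarchy.modules
                                if m.parent is None).genes)
            cats = epi_mod.categorize_modules(
                hierarchy, degs, dmcs, mapping, universe,
                (self.cfg.min_module_size, self.cfg.max_module_size),
                self.cfg.min_overlap, self.cfg.enrichment_alpha)
            cats.to_csv(self.out / f"{label}.module_regulation.tsv",
                        sep="\t", index=False)
            self.manifest["stages"].setdefault("epigenomics", {})[label] = {
                "deg_up": int((degs["direction"] == "up").sum()),
                "deg_down": int((degs["direction"] == "down").sum()),
                "dmc_up": int((dmcs["direction"] == "up").sum()),
                "dmc_down": int((dmcs["direction"] == "down").sum())}
        self._write_manifest()

    def run_chromatin(self) -> None:
        bands = pio.read_cytoband(
            _require(self.input_dir / "cytoband.tsv", "simulate"))
        peaks = pio.read_peaks(
            _require(self.input_dir / "peaks.bed", "simulate"),
            _require(self.input_dir / "peaks.counts.tsv", "simulate"))
        signal = chrom_mod.cytoband_peak_signal(peaks, bands)
        fc = chrom_mod.fold_change_vs_background(signal, peaks)
        pd.DataFrame({"signal": signal, "fold_change": fc}).to_csv(
            self.out / "cytoband_signal.tsv", sep="\t", index_label="band")
        enriched: set[str] = set()
        for label in self.cohorts:
            path = self.out / f"{label}.cytoband_enrichment.tsv"
            _require(path, "enrichment")
            tab = pd.read_csv(path, sep="\t")
            if len(tab):
                enriched |= set(tab.loc[tab["significant"], "set_id"])
        result = chrom_mod.compare_enriched_vs_depleted(fc, enriched)
        pio.write_json({"statistic": result.statistic, "p": result.p,
                        "median_enriched": result.median_enriched,
                        "median_depleted": result.median_depleted,
                        "n_enriched": result.n_enriched,
                        "n_depleted": result.n_depleted,
                        "method": result.method},
                       self.out / "chromatin_comparison.json")
        self.manifest["stages"]["chromatin"] = {
            "enriched_bands": len(enriched), "wilcoxon_p": result.p}
        self._write_manifest()

    def run_preservation(self) -> None:
        hierarchies = {}
        networks = {}
        for label in self.cohorts:
            hierarchies[label] = _read_module_table(
                _require(self.out / f"{label}.modules.tsv", "network"))
            edges = pd.read_csv(
                _require(self.out / f"{label}.edges.tsv", "network"),
                sep="\t")
            G = nx.Graph()
            for row in edges.itertuples(index=False):
                G.add_edge(row.gene_a, row.gene_b, weight=row.abs_r,
                           r=row.r)
            networks[label] = G
        pairs = pres_mod.pairwise_similarity(
            hierarchies, (self.cfg.min_module_size, self.cfg.max_module_size),
            self.cfg.jaccard_conserved, self.cfg.preservation_alpha)
        pairs.to_csv(self.out / "preservation_pairs.tsv", sep="\t",
                     index=False)
        classes = pres_mod.classify_modules(
            pairs, self.cfg.jaccard_conserved, self.cfg.jaccard_specific,
            self.cfg.preservation_alpha)
        classes.to_csv(self.out / "module_classes.tsv", sep="\t", index=False)
        clusters = pres_mod.greedy_module_clusters(pairs, seed=self.cfg.seed)
        pio.write_json(pres_mod.clusters_to_json(clusters),
                       self.out / "module_clusters.json")
        if len(self.cohorts) >= 2:
            co = pres_mod.cluster_cohorts(pairs, clusters,
                                          cut=self.cfg.cohort_cluster_cut)
            pio.write_json({"groups": co["groups"],
                            "cohorts": co["cohorts"],
                            "linkage": co["linkage"].tolist()},
                           self.out / "cohort_clusters.json")
        conserved_ids = classes[classes["label"] == "conserved"]
        targets = {
            label: [set(hierarchies[label].by_id()[m].genes)
                    for m in conserved_ids.loc[conserved_ids["cohort"]
                                               == label, "module"]]
            for label in self.cohorts}
        if any(targets.values()):
            agg = pres_mod.aggregate_network(
                targets, networks, self.cfg.min_aggregation_weight)
            rows = [{"gene_a": min(u, v), "gene_b": max(u, v),
                     "weight": d["weight"]}
                    for u, v, d in agg.edges(data=True)]
            agg_edges = pd.DataFrame(rows, columns=["gene_a", "gene_b",
                                                    "weight"])
            if len(agg_edges):
                agg_edges = agg_edges.sort_values(
                    ["gene_a", "gene_b"]).reset_index(drop=True)
            agg_edges.to_csv(self.out / "aggregated_network.tsv", sep="\t",
                             index=False)
            agg_nodes = pd.DataFrame(
                sorted(({"gene": n, "weight": d["weight"]}
                        for n, d in agg.nodes(data=True)),
                       key=lambda r: r["gene"]))
            agg_nodes.to_csv(self.out / "aggregated_nodes.tsv", sep="\t",
                             index=False)
        self.manifest["stages"]["preservation"] = {
            "pairs": int(len(pairs)),
            "conserved_pairs": int(pairs["conserved"].sum()),
            "conserved_modules":
                int((classes["label"] == "conserved").sum()),
            "specific_modules": int((classes["label"] == "specific").sum()),
            "clusters": len(clusters)}
        self._write_manifest()

    # --------------------------------------------------------------- all

    def run_all(self) -> Path:
        self.run_preprocess()
        self.run_network()
        self.run_enrichment()
        self.run_prognosis()
        self.run_epigenomics()
        self.run_chromatin()
        self.run_preservation()
        self.manifest["completed"] = STAGES
        self._write_manifest()
        return self.out


def run_pipeline(config: PipelineConfig) -> Path:
    return Pipeline(config).run_all()
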