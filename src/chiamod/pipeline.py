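"""End-to-end orchestration of the chromatin-network workflow.

The stages mirror the hierarchical analysis: filter PET interactions
(replicate intersection, inter-chromosomal removal, self-ligation cutoff),
build and annotate the chromatin graph, compute node metrics, cluster the
biggest connected component of each chromosome with the MSM method
(optionally optimizing {theta, alpha} by the MI ratio), and run module
enrichment.  Every artifact and every derived seed is recorded in a
manifest so a run is reproducible from its config alone.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import graph_build, network_metrics, pet_filtering
from .enrichment import enrich_modules, read_gmt
from .mi_objective import (PairMICache, clustering_mi_ratio, mi_ratio,
                           optimize_parameters, MIRatioReport)
from .msm_clustering import UNASSIGNED, cluster_component

_STAGE_SEED_STRIDE = 1_000_003


def derive_seed(global_seed: int, stage_index: int) -> int:
    return (int(global_seed) + stage_index * _STAGE_SEED_STRIDE) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (round-trips through YAML/JSON)."""

    out_dir: str
    rep1: str | None = None
    rep2: str | None = None
    genes: str | None = None
    lncrnas: str | None = None
    states: str | None = None
    expression: str | None = None
    gmt: str | None = None
    simulate: dict | None = None          # synthetic-bundle spec overrides
    cutoff_nt: float | None = None
    fit_cutoff: bool = False
    alpha: float = 500.0
    theta: float = 0.7
    alpha_grid: list | None = None
    theta_grid: list | None = None
    pair_scope: str = "gene"
    min_component_nodes: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.cutoff_nt is not None and self.fit_cutoff:
            raise ValueError("set either cutoff_nt or fit_cutoff, not both")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and writes) the manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "artifacts": {}}

    if config.simulate is not None:
        from .synthetic_data import write_fixture_bundle
        sim_seed = derive_seed(config.seed, 0)
        sim_dir = os.path.join(config.out_dir, "sim")
        paths = write_fixture_bundle(sim_dir, seed=sim_seed,
                                     **config.simulate)
        config = _with_paths(config, paths)
        manifest["stages"]["simulate"] = {"seed": sim_seed, "paths": paths}

    # --- filter ------------------------------------------------------------
    if config.rep1 is None:
        raise ValueError("no interaction input: set rep1 (and rep2) or simulate")
    rep1 = pet_filtering.read_interactions(config.rep1)
    counts = {"rep1": len(rep1)}
    merged = rep1
    if config.rep2:
        rep2 = pet_filtering.read_interactions(config.rep2)
        counts["rep2"] = len(rep2)
        merged = pet_filtering.intersect_replicates(rep1, rep2)
    counts["after_replicate_intersection"] = len(merged)
    merged, frac_inter = pet_filtering.filter_interchromosomal(merged)
    counts["after_interchromosomal_filter"] = len(merged)

    fit_info = None
    if config.fit_cutoff:
        fit = pet_filtering.fit_distance_breakpoint(
            pet_filtering.pet_distances(merged))
        cutoff = fit.breakpoint_nt
        fit_info = {"breakpoint_nt": fit.breakpoint_nt,
                    "slope_lo": fit.slope_lo, "slope_hi": fit.slope_hi,
                    "reliable": fit.reliable}
    else:
        cutoff = config.cutoff_nt if config.cutoff_nt is not None else 1691.0
    filtered, n_self = pet_filtering.filter_self_ligation(merged, cutoff)
    counts["after_self_ligation_filter"] = len(filtered)

    filtered_path = os.path.join(config.out_dir, "filtered.bedpe")
    filtered.to_bedpe(filtered_path)
    report = {"fraction_interchromosomal_removed": frac_inter,
              "cutoff_nt": cutoff, "n_self_ligation_removed": n_self,
              "breakpoint_fit": fit_info, "counts": counts}
    report_path = os.path.join(config.out_dir, "filter_report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1)
    manifest["stages"]["filter"] = report
    manifest["artifacts"]["filtered"] = filtered_path
    manifest["artifacts"]["filter_report"] = report_path

    # --- build -------------------------------------------------------------
    nodes, anchor_map = graph_build.merge_anchors(filtered)
    g = graph_build.build_graph(filtered, nodes, anchor_map)
    tracks = []
    if config.genes:
        tracks.append(_read_track(config.genes, "gene"))
    if config.lncrnas:
        tracks.append(_read_track(config.lncrnas, "lncRNA"))
    if config.states:
        tracks.append(graph_build.read_bed_track(config.states))
    if tracks:
        graph_build.annotate_nodes(g, tracks)
    graph_dir = os.path.join(config.out_dir, "graph")
    manifest["artifacts"].update(graph_build.write_graph(g, graph_dir))
    manifest["stages"]["build"] = {
        "n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges(),
        "n_self_loops_dropped": g.graph.get("n_self_loops_dropped", 0)}

    # --- metrics -----------------------------------------------------------
    metrics = network_metrics.metrics_table(g)
    metrics_path = os.path.join(config.out_dir, "metrics.tsv")
    metrics.to_csv(metrics_path, sep="\t", index=False)
    manifest["artifacts"]["metrics"] = metrics_path

    # --- clustering / optimization -----------------------------------------
    expr = None
    if config.expression:
        expr = pd.read_csv(config.expression, sep="\t", index_col=0)
    cluster_seed = derive_seed(config.seed, 1)
    clusterings = {}
    summary_rows = []
    for chrom in sorted({d["chrom"] for _, d in g.nodes(data=True)}):
        sub = graph_build.chromosome_subgraph(g, chrom)
        comps = graph_build.connected_components(sub)
        if not comps:
            continue
        component = sub.subgraph(comps[0]).copy()
        if component.number_of_nodes() < config.min_component_nodes:
            continue
        if expr is not None and config.alpha_grid and config.theta_grid:
            result = optimize_parameters(
                component, expr, config.alpha_grid, config.theta_grid,
                seed=cluster_seed, pair_scope=config.pair_scope,
                min_nodes=config.min_component_nodes)
            clustering = result.best_clustering
            grid_path = os.path.join(config.out_dir, f"grid_{chrom}.tsv")
            result.table.to_csv(grid_path, sep="\t", index=False)
            manifest["artifacts"][f"grid_{chrom}"] = grid_path
            ratio = result.best_ratio
        else:
            clustering = cluster_component(
                component, config.alpha, config.theta, seed=cluster_seed,
                min_nodes=config.min_component_nodes)
            ratio = None
            if expr is not None:
                rep = clustering_mi_ratio(clustering, component, expr,
                                          pair_scope=config.pair_scope)
                ratio = rep.ratio if rep.defined else None
        clusterings[chrom] = (component, clustering)
        cpath = os.path.join(config.out_dir, f"clustering_{chrom}.tsv")
        clustering.to_frame().to_csv(cpath, sep="\t", index=False)
        manifest["artifacts"][f"clustering_{chrom}"] = cpath
        summary_rows.append({
            "chrom": chrom, "n_nodes": component.number_of_nodes(),
            "m": clustering.m, "alpha": clustering.alpha,
            "theta": clustering.theta,
            "n_transition": int(len(clustering.transition_region)),
            "mi_ratio": ratio, "seed": cluster_seed})
    manifest["stages"]["cluster"] = summary_rows

    # --- enrichment ---------------------------------------------------------
    if config.gmt and clusterings:
        gene_sets = read_gmt(config.gmt)
        enrich_summary = {}
        for chrom, (component, clustering) in clusterings.items():
            results = enrich_modules(component, clustering.assignment_by_node(),
                                     gene_sets)
            for module, table in results.items():
                path = os.path.join(config.out_dir,
                                    f"enrichment_{chrom}_module{module}.tsv")
                table.to_csv(path, sep="\t", index=False)
                manifest["artifacts"][f"enrichment_{chrom}_m{module}"] = path
                enrich_summary[f"{chrom}:m{module}"] = int(table["reported"].sum())
        manifest["stages"]["enrich"] = enrich_summary

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=_json_default)
    manifest["artifacts"]["manifest"] = manifest_path
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _read_track(path, feature_class):
    if path.endswith((".gtf", ".gff", ".gff3")):
        return graph_build.read_gtf_track(path, feature_class)
    return graph_build.read_bed_track(path, feature_class)


def _with_paths(config: PipelineConfig, paths: dict) -> PipelineConfig:
    from dataclasses import replace
    return replace(config, rep1=paths["rep1"], rep2=paths["rep2"],
                   genes=paths["genes"], lncrnas=paths["lncrnas"],
                   states=paths["states"],
                   expression=config.expression or paths["expression"],
                   gmt=config.gmt or paths["gmt"], simulate=None)


def read_partition(path) -> dict:
    """Read an external hard partition (TSV: node_id, module_id)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("partition file needs node_id and module_id columns")
    node_col, mod_col = df.columns[:2]
    out = {}
    for row in df.itertuples(index=False):
        mod = getattr(row, mod_col)
        node = getattr(row, node_col)
        out[node] = UNASSIGNED if str(mod) == "UNASSIGNED" else int(mod)
    return out


def score_external_partition(partition: dict, g, expr: pd.DataFrame,
                             pair_scope: str = "gene",
                             mi_cache: PairMICache | None = None) -> MIRatioReport:
    """MI-ratio score of any externally supplied partition, computed with
    the same protocol as for MSM clusterings (enables method comparison)."""
    missing = [n for n in partition if n not in g.nodes]
    if missing:
        raise ValueError(f"partition nodes absent from graph: {missing[:10]}")
    return mi_ratio(partition, g, expr, pair_scope=pair_scope,
                    mi_cache=mi_cache)
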