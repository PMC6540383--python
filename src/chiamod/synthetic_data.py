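"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the stages of the analysis:

* a planted-module chromatin graph (stochastic block model with annotation
  classes and synthetic genomic coordinates),
* PET genomic distances drawn from a two-regime bounded power-law mixture
  with a planted breakpoint (the self-/inter-ligation picture),
* an RPKM expression matrix across tissues whose rows are correlated
  within planted modules.

``write_fixture_bundle`` lays these out on disk in exactly the formats the
pipeline reads (BEDPE, BED6, TSV, GMT) together with a truth JSON, so the
whole workflow can be exercised end-to-end without any external data.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph_build import CLASS_ORDER, composite_label

ANNOTATION_CLASSES = ("gene", "lncRNA", "lncRNA_enhancer", "enhancer", "unknown")

#: class set attached to nodes of each simulated annotation class
_CLASS_SETS = {
    "gene": frozenset({"gene"}),
    "lncRNA": frozenset({"lncRNA"}),
    "lncRNA_enhancer": frozenset({"lncRNA", "enhancer"}),
    "enhancer": frozenset({"enhancer"}),
    "unknown": frozenset(),
}


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Planted-partition graph with annotation classes.

    ``p_in``/``p_out`` are within-/between-module edge probabilities;
    ``label_fractions`` maps annotation classes to fractions summing to 1.
    """

    module_sizes: tuple[int, ...] = (30, 30, 30)
    p_in: float = 0.25
    p_out: float = 0.005
    label_fractions: dict = field(default_factory=lambda: {
        "gene": 0.4, "lncRNA": 0.2, "lncRNA_enhancer": 0.1,
        "enhancer": 0.15, "unknown": 0.15})
    seed: int = 0

    def __post_init__(self):
        if len(self.module_sizes) == 0 or any(s < 1 for s in self.module_sizes):
            raise ValueError("module_sizes must be non-empty positive integers")
        for p, name in ((self.p_in, "p_in"), (self.p_out, "p_out")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.label_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("label_fractions must sum to 1")
        unknown = set(self.label_fractions) - set(ANNOTATION_CLASSES)
        if unknown:
            raise ValueError(f"unknown annotation classes: {sorted(unknown)}")


@dataclass(frozen=True)
class DistanceMixtureSpec:
    """Two-regime bounded power-law mixture of PET genomic distances.

    The exponents are the slopes of log10(count per logarithmic bin) vs
    log10(distance) below/above the planted breakpoint — the quantity a
    two-line fit on the log-log histogram estimates.  ``mix_weight`` is
    the self-ligation (below-breakpoint) fraction; ``None`` chooses the
    weight that makes the two regimes' histogram heights continuous at the
    breakpoint, so the fitted lines cross at the plant.
    """

    n: int = 50_000
    breakpoint_nt: int = 1691
    exponent_self: float = -0.5
    exponent_inter: float = -2.0
    d_min: float = 50.0
    d_max: float = 2e7
    mix_weight: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not self.d_min < self.breakpoint_nt < self.d_max:
            raise ValueError("need d_min < breakpoint_nt < d_max")
        if self.exponent_self >= 0 or self.exponent_inter >= 0:
            raise ValueError("power-law slopes must be negative on the log-log scale")
        if self.mix_weight is not None and not 0.0 <= self.mix_weight <= 1.0:
            raise ValueError("mix_weight must be in [0, 1]")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Module-correlated RPKM expression profiles across tissues."""

    n_samples: int = 24
    intra_corr: float = 0.8
    noise_sd: float = 1.0
    baseline_logrpkm_mean: float = 1.0
    baseline_logrpkm_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if not 0.0 <= self.intra_corr < 1.0:
            raise ValueError("intra_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def gen_planted_graph(spec: PlantedNetworkSpec) -> tuple[nx.Graph, np.ndarray]:
    """Sample a planted-module chromatin graph.

    Returns an undirected simple graph whose nodes carry synthetic genomic
    coordinates (non-overlapping anchors on one synthetic chromosome),
    annotation classes drawn from ``label_fractions`` and the planted
    module id, plus the planted-label vector.
    """
    sizes = list(spec.module_sizes)
    k = len(sizes)
    p = [[spec.p_in if i == j else spec.p_out for j in range(k)]
         for i in range(k)]
    g = nx.stochastic_block_model(sizes, p, seed=spec.seed)
    g = nx.Graph(g)  # drop SBM bookkeeping, keep a plain simple graph

    n = g.number_of_nodes()
    labels = np.concatenate([np.full(s, i, dtype=int)
                             for i, s in enumerate(sizes)])
    rng = np.random.default_rng(spec.seed)
    classes = _allocate_classes(spec.label_fractions, n, rng)

    spacing, anchor_len = 5000, 1000
    for v in g.nodes:
        start = 10_000 + v * spacing
        cls = classes[v]
        attrs = {
            "chrom": "chr1",
            "start": start,
            "end": start + anchor_len,
            "classes": set(_CLASS_SETS[cls]) or {"unknown"},
            "gene_names": [f"GENE{v}"] if "gene" in _CLASS_SETS[cls] else [],
            "lncrna_names": [f"LNC{v}"] if "lncRNA" in _CLASS_SETS[cls] else [],
            "planted_module": int(labels[v]),
            "sim_class": cls,
        }
        attrs["composite_label"] = composite_label(attrs["classes"])
        g.nodes[v].update(attrs)
    return g, labels


def _allocate_classes(fractions: dict, n: int, rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of class counts, then a seeded shuffle."""
    names = [c for c in ANNOTATION_CLASSES if c in fractions]
    quotas = [fractions[c] * n for c in names]
    counts = [int(math.floor(q)) for q in quotas]
    remainders = np.array(quotas) - np.array(counts)
    for i in np.argsort(-remainders)[: n - sum(counts)]:
        counts[i] += 1
    pool = [c for c, m in zip(names, counts) for _ in range(m)]
    rng.shuffle(pool)
    return pool


def _bounded_powerlaw(u: np.ndarray, slope: float, lo: float, hi: float) -> np.ndarray:
    """Inverse-CDF sampling of density x^(slope-1) on [lo, hi].

    ``slope`` is the log-log slope of counts per logarithmic bin; the
    corresponding density per unit x is x^(slope-1).
    """
    s = slope
    if abs(s) < 1e-12:  # log-uniform
        return lo * (hi / lo) ** u
    return (u * (hi ** s - lo ** s) + lo ** s) ** (1.0 / s)


def _log_bin_height(slope: float, lo: float, hi: float, x: float) -> float:
    """Probability density per unit log10(x) at x for the bounded regime."""
    s = slope
    if abs(s) < 1e-12:
        return 1.0 / math.log10(hi / lo)
    c = s / (hi ** s - lo ** s)
    return c * x ** s * math.log(10.0)


def continuity_mix_weight(spec: DistanceMixtureSpec) -> float:
    """Self-ligation weight that makes the two regimes' log-log histogram
    heights equal at the breakpoint."""
    h_self = _log_bin_height(spec.exponent_self, spec.d_min,
                             spec.breakpoint_nt, spec.breakpoint_nt)
    h_inter = _log_bin_height(spec.exponent_inter, spec.breakpoint_nt,
                              spec.d_max, spec.breakpoint_nt)
    r = h_inter / h_self
    return r / (1.0 + r)


def gen_pet_distances(spec: DistanceMixtureSpec) -> np.ndarray:
    """Draw ``n`` PET distances (nt, positive integers) from the planted
    two-power-law mixture."""
    rng = np.random.default_rng(spec.seed)
    w = continuity_mix_weight(spec) if spec.mix_weight is None else spec.mix_weight
    is_self = rng.random(spec.n) < w
    u = rng.random(spec.n)
    d = np.empty(spec.n)
    d[is_self] = _bounded_powerlaw(u[is_self], spec.exponent_self,
                                   spec.d_min, spec.breakpoint_nt)
    d[~is_self] = _bounded_powerlaw(u[~is_self], spec.exponent_inter,
                                    spec.breakpoint_nt, spec.d_max)
    return np.maximum(np.round(d), 1).astype(np.int64)


def gen_expression(planted_labels, classes, spec: ExpressionSimSpec) -> pd.DataFrame:
    """Simulate an RPKM matrix whose rows are correlated within modules.

    One row per expressed feature (gene/lncRNA names of gene- or
    lncRNA-class nodes).  Log-scale model: a shared per-module latent
    profile plus independent Gaussian noise, with the signal amplitude set
    so the expected within-module pairwise correlation equals
    ``intra_corr``; exponentiation then gives non-negative, right-skewed
    RPKM values.
    """
    planted_labels = np.asarray(planted_labels)
    if len(planted_labels) != len(classes):
        raise ValueError("one planted label per node is required")
    rng = np.random.default_rng(spec.seed)
    modules = sorted(set(int(m) for m in planted_labels))
    latent = {m: rng.standard_normal(spec.n_samples) for m in modules}
    rho = spec.intra_corr
    signal_sd = spec.noise_sd * math.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0

    rows, index = [], []
    for v, (module, cls) in enumerate(zip(planted_labels, classes)):
        names = []
        if "gene" in _CLASS_SETS.get(cls, frozenset({cls})) or cls == "gene":
            names.append(f"GENE{v}")
        if "lncRNA" in _CLASS_SETS.get(cls, frozenset()):
            names.append(f"LNC{v}")
        for name in names:
            baseline = (spec.baseline_logrpkm_mean
                        + spec.baseline_logrpkm_sd * rng.standard_normal())
            log_rpkm = (baseline
                        + signal_sd * latent[int(module)]
                        + spec.noise_sd * rng.standard_normal(spec.n_samples))
            rows.append(np.exp(log_rpkm))
            index.append(name)
    columns = [f"tissue{j + 1:02d}" for j in range(spec.n_samples)]
    return pd.DataFrame(rows, index=pd.Index(index, name="feature_id"),
                        columns=columns)


def write_fixture_bundle(out_dir,
                         network_spec: PlantedNetworkSpec | None = None,
                         distance_spec: DistanceMixtureSpec | None = None,
                         expression_spec: ExpressionSimSpec | None = None,
                         replicate_dropout: float = 0.10,
                         interchrom_fraction: float = 0.018,
                         n_self_ligation: int = 30,
                         seed: int = 0) -> dict:
    """Write a complete, internally consistent fixture bundle.

    Emits two pseudo-replicate BEDPE files (replicate 2 drops a seeded
    ``replicate_dropout`` fraction of the master interactions; both contain
    the same planted inter-chromosomal and self-ligation contaminants so
    the downstream filters, not the intersection, must remove them), BED6
    gene/lncRNA tracks, a chromHMM-style state BED, an expression TSV, a
    GMT with one gene set per planted module plus a background term, and a
    truth JSON.  Returns the path map.
    """
    network_spec = network_spec or PlantedNetworkSpec(seed=seed)
    distance_spec = distance_spec or DistanceMixtureSpec(seed=seed)
    expression_spec = expression_spec or ExpressionSimSpec(seed=seed)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)

    g, labels = gen_planted_graph(network_spec)
    nodes = sorted(g.nodes)
    coords = {v: (g.nodes[v]["chrom"], g.nodes[v]["start"], g.nodes[v]["end"])
              for v in nodes}

    master = []
    for u, v in sorted(g.edges):
        master.append(coords[u] + coords[v])
    # contaminants removed by the filters, present in both replicates
    n_inter = max(1, round(interchrom_fraction * len(master)
                           / max(1e-9, 1 - interchrom_fraction)))
    for i in range(n_inter):
        s1 = 10_000 + int(rng.integers(0, 1_000_000))
        s2 = 10_000 + int(rng.integers(0, 1_000_000))
        master.append(("chr1", s1, s1 + 1000, "chr2", s2, s2 + 1000))
    short = []
    for _ in range(n_self_ligation):
        v = int(rng.choice(nodes))
        c, s, e = coords[v]
        short.append((c, s, e, c, s + 500, e + 500))  # midpoint distance 500 nt
    master.extend(short)

    rep1 = master
    n_drop = int(round(replicate_dropout * len(master)))
    drop = set(rng.choice(len(master), size=n_drop, replace=False).tolist())
    rep2 = [rec for i, rec in enumerate(master) if i not in drop]

    paths = {
        "rep1": os.path.join(out_dir, "interactions_rep1.bedpe"),
        "rep2": os.path.join(out_dir, "interactions_rep2.bedpe"),
        "genes": os.path.join(out_dir, "genes.bed"),
        "lncrnas": os.path.join(out_dir, "lncrnas.bed"),
        "states": os.path.join(out_dir, "states.bed"),
        "expression": os.path.join(out_dir, "expression.tsv"),
        "gmt": os.path.join(out_dir, "genesets.gmt"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    for key, records in (("rep1", rep1), ("rep2", rep2)):
        with open(paths[key], "w") as fh:
            for rec in records:
                fh.write("\t".join(str(x) for x in rec) + "\n")

    with open(paths["genes"], "w") as gfh, open(paths["lncrnas"], "w") as lfh:
        for v in nodes:
            c, s, e = coords[v]
            for name in g.nodes[v]["gene_names"]:
                gfh.write(f"{c}\t{s}\t{e}\t{name}\t0\t+\n")
            for name in g.nodes[v]["lncrna_names"]:
                lfh.write(f"{c}\t{s}\t{e}\t{name}\t0\t-\n")
    with open(paths["states"], "w") as fh:
        for v in nodes:
            c, s, e = coords[v]
            if "enhancer" in g.nodes[v]["classes"]:
                fh.write(f"{c}\t{s}\t{e}\tenhancer\n")
        # a repressed segment the annotator must ignore
        fh.write("chr1\t0\t5000\trepressed\n")

    classes = [g.nodes[v]["sim_class"] for v in nodes]
    expr = gen_expression(labels, classes, expression_spec)
    expr.to_csv(paths["expression"], sep="\t")

    module_genes: dict[int, list[str]] = {}
    for v in nodes:
        for name in g.nodes[v]["gene_names"]:
            module_genes.setdefault(int(labels[v]), []).append(name)
    all_genes = sorted(n for names in module_genes.values() for n in names)
    with open(paths["gmt"], "w") as fh:
        for m, names in sorted(module_genes.items()):
            fh.write("\t".join([f"MODULE{m}_TERM", f"planted module {m} genes"]
                               + sorted(names)) + "\n")
        background = list(rng.choice(all_genes,
                                     size=min(15, len(all_genes)), replace=False))
        fh.write("\t".join(["BACKGROUND_TERM", "random background genes"]
                           + sorted(background)) + "\n")

    truth = {
        "planted_labels": {str(v): int(labels[v]) for v in nodes},
        "n_nodes": len(nodes),
        "n_edges": g.number_of_edges(),
        "breakpoint_nt": distance_spec.breakpoint_nt,
        "n_interchromosomal": n_inter,
        "n_self_ligation": n_self_ligation,
        "n_master": len(master),
        "n_rep2": len(rep2),
        "module_sizes": list(network_spec.module_sizes),
        "seed": seed,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
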