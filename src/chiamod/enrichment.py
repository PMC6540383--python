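"""Hypergeometric term enrichment for module gene sets.

For a module of n genes drawn from a background universe of N genes, a
term annotating K universe genes with k of them in the module has the
one-sided upper-tail hypergeometric p-value P[X >= k].  P-values are
Benjamini-Hochberg adjusted across the tested terms; a term is *reported*
when its adjusted p-value is at most 0.1 and more than two module genes
carry it.  Reported terms propagate to lncRNAs of the same module, and
transition-region nodes inherit the union of reported terms of the
modules containing their direct gene neighbors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .msm_clustering import UNASSIGNED

REPORT_ADJ_P = 0.1
REPORT_MIN_GENES = 3  # "more than two genes" => k > 2


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term, description, member genes."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT rows need term, "
                                 "description and >= 1 gene")
            sets[fields[0]] = set(fields[2:])
    return sets


def bh_adjust(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(module_genes, gene_sets: dict,
                         universe) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of a module's gene set.

    Gene sets are intersected with the universe; terms with no universe
    members are skipped.  Returns one row per tested term with k, K, n,
    N, p, adjusted p and the reported flag.
    """
    universe = set(universe)
    module = set(module_genes)
    if not universe:
        raise ValueError("empty background universe")
    if not module:
        raise ValueError("empty module gene set")
    if not module <= universe:
        raise ValueError("module genes must be a subset of the universe")
    N, n = len(universe), len(module)
    rows = []
    for term, members in sorted(gene_sets.items()):
        members = set(members) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(module & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(1.0, p)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_value"])
    if len(df):
        df["adjusted_p"] = bh_adjust(df["p_value"].to_numpy())
        df["reported"] = (df["adjusted_p"] <= REPORT_ADJ_P) \
            & (df["k"] >= REPORT_MIN_GENES)
    else:
        df["adjusted_p"] = []
        df["reported"] = []
    return df


def module_gene_sets(g, assignment_by_node: dict) -> dict[int, set[str]]:
    """Gene symbols per module (multi-gene nodes contribute each gene
    once; transition-region nodes contribute nowhere)."""
    out: dict[int, set[str]] = {}
    for node, module in assignment_by_node.items():
        if module is None or module == UNASSIGNED:
            continue
        out.setdefault(int(module), set()).update(
            g.nodes[node].get("gene_names", []))
    return {m: genes for m, genes in out.items() if genes}


def enrich_modules(g, assignment_by_node: dict, gene_sets: dict,
                   universe=None) -> dict[int, pd.DataFrame]:
    """Run hypergeometric enrichment for every module.

    The default background universe is every gene present on a graph
    node (enrichment relative to the network).
    """
    if universe is None:
        universe = {name for _, d in g.nodes(data=True)
                    for name in d.get("gene_names", [])}
    results = {}
    for module, genes in sorted(module_gene_sets(g, assignment_by_node).items()):
        results[module] = hypergeom_enrichment(genes, gene_sets, universe)
    return results


def reported_terms(enrichment: pd.DataFrame) -> set[str]:
    if len(enrichment) == 0:
        return set()
    return set(enrichment.loc[enrichment["reported"], "term"])


def transfer_annotation(node, g, assignment_by_node: dict,
                        enrichment_by_module: dict) -> list[str]:
    """Inherited term list for a node.

    Assigned nodes (used for lncRNAs without their own annotation)
    inherit their module's reported terms.  Transition-region nodes
    inherit the union of reported terms of the modules containing their
    direct gene neighbors.
    """
    module = assignment_by_node.get(node, UNASSIGNED)
    terms: set[str] = set()
    if module is not None and module != UNASSIGNED:
        if module in enrichment_by_module:
            terms = reported_terms(enrichment_by_module[module])
    else:
        for nb in g.neighbors(node):
            if not g.nodes[nb].get("gene_names"):
                continue
            nb_module = assignment_by_node.get(nb, UNASSIGNED)
            if nb_module is None or nb_module == UNASSIGNED:
                continue
            if nb_module in enrichment_by_module:
                terms |= reported_terms(enrichment_by_module[nb_module])
    return sorted(terms)
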