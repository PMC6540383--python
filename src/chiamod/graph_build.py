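"""Chromatin graph construction and node annotation.

Anchors of the filtered PET interactions that overlap by >= 1 bp on the
same chromosome are merged into single genomic-region nodes; interactions
become edges of an undirected simple graph (parallel interactions collapse,
within-node interactions are dropped as would-be self-loops).  Nodes are
then annotated by strand-ignored interval overlap with gene, lncRNA and
chromHMM-style chromatin-state tracks: a node's class set is the union of
classes of all overlapping features, the "repressed" state carries no
information in a Pol II-mediated network and is dropped, and nodes with no
overlap at all are labeled "unknown".  Class sets are rendered into a
deterministic composite label such as ``lncRNA_enhancer``.
"""

from __future__ import annotations

import pandas as pd
import networkx as nx
from intervaltree import IntervalTree

from .pet_filtering import InteractionSet

#: deterministic ordering of annotation classes inside composite labels
CLASS_ORDER = ("gene", "lncRNA", "enhancer", "weak_enhancer", "TSS",
               "promoter_flanking", "CTCF", "transcribed")

KNOWN_CLASSES = set(CLASS_ORDER) | {"unknown", "repressed"}

TRACK_COLUMNS = ["chrom", "start", "end", "strand", "feature_class", "name"]


def composite_label(classes: set[str]) -> str:
    """Render a class set into the canonical underscore-joined label."""
    ordered = [c for c in CLASS_ORDER if c in classes]
    return "_".join(ordered) if ordered else "unknown"


# ---------------------------------------------------------------------------
# annotation tracks

def make_track(records) -> pd.DataFrame:
    """Build an annotation track from (chrom, start, end, strand,
    feature_class, name) records, validating the feature classes."""
    df = pd.DataFrame(list(records), columns=TRACK_COLUMNS)
    bad = set(df["feature_class"]) - KNOWN_CLASSES
    if bad:
        raise ValueError(f"unknown feature classes in track: {sorted(bad)}")
    return df


def read_bed_track(path, feature_class: str | None = None) -> pd.DataFrame:
    """Read a BED file into an annotation track.

    With ``feature_class`` given (gene/lncRNA tracks) the BED name column
    holds the feature name.  Without it (chromatin-state segmentations)
    the name column holds the state label, normalized to the canonical
    class vocabulary.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >= 4 columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "."
            if feature_class is None:
                cls = normalize_state_label(name)
                rows.append((chrom, start, end, strand, cls, name))
            else:
                rows.append((chrom, start, end, strand, feature_class, name))
    return make_track(rows)


_STATE_ALIASES = {
    "enhancer": "enhancer", "enh": "enhancer", "e": "enhancer",
    "weak_enhancer": "weak_enhancer", "weakenhancer": "weak_enhancer",
    "we": "weak_enhancer",
    "tss": "TSS",
    "promoter_flanking": "promoter_flanking", "promoterflanking":
        "promoter_flanking", "pf": "promoter_flanking",
    "ctcf": "CTCF",
    "transcribed": "transcribed", "t": "transcribed", "tx": "transcribed",
    "repressed": "repressed", "r": "repressed",
}


def normalize_state_label(label: str) -> str:
    key = label.strip().lower().replace("-", "_").replace(" ", "_")
    if key not in _STATE_ALIASES:
        raise ValueError(f"unrecognized chromatin-state label: {label!r}")
    return _STATE_ALIASES[key]


def read_gtf_track(path, feature_class: str,
                   feature_types: tuple[str, ...] = ("gene",)) -> pd.DataFrame:
    """Read gene/lncRNA bodies from a GTF (1-based inclusive -> converted
    to 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in feature_types:
                continue
            name = _gtf_attribute(f[8], "gene_name") or \
                _gtf_attribute(f[8], "gene_id") or "NA"
            rows.append((f[0], int(f[3]) - 1, int(f[4]), f[6],
                         feature_class, name))
    return make_track(rows)


def _gtf_attribute(attributes: str, key: str) -> str | None:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    return None


# ---------------------------------------------------------------------------
# graph construction

def merge_anchors(s: InteractionSet) -> tuple[pd.DataFrame, dict]:
    """Merge anchors overlapping by >= 1 bp into genomic-region nodes.

    Returns the node table (node_id, chrom, start, end) and a map from
    every distinct anchor (chrom, start, end) to its node id.  Merging is
    transitive: a chain of pairwise-overlapping anchors collapses into one
    union interval.
    """
    anchors = set()
    for row in s.df.itertuples(index=False):
        anchors.add((row.chrom_a, row.start_a, row.end_a))
        anchors.add((row.chrom_b, row.start_b, row.end_b))

    per_chrom: dict[str, list[tuple[int, int, tuple]]] = {}
    for chrom, start, end in anchors:
        per_chrom.setdefault(chrom, []).append((start, end, (chrom, start, end)))

    node_rows, anchor_to_node = [], {}
    node_id = 0
    for chrom in sorted(per_chrom):
        ivs = sorted(per_chrom[chrom])
        cur_start, cur_end = ivs[0][0], ivs[0][1]
        members = [ivs[0][2]]
        for start, end, key in ivs[1:]:
            if start < cur_end:  # >= 1 bp overlap (half-open intervals)
                cur_end = max(cur_end, end)
                members.append(key)
            else:
                node_rows.append((node_id, chrom, cur_start, cur_end))
                for m in members:
                    anchor_to_node[m] = node_id
                node_id += 1
                cur_start, cur_end, members = start, end, [key]
        node_rows.append((node_id, chrom, cur_start, cur_end))
        for m in members:
            anchor_to_node[m] = node_id
        node_id += 1
    nodes = pd.DataFrame(node_rows, columns=["node_id", "chrom", "start", "end"])
    return nodes, anchor_to_node


def build_graph(s: InteractionSet, nodes: pd.DataFrame,
                anchor_to_node: dict) -> nx.Graph:
    """Build the chromatin graph: one node per merged region, one edge per
    interacting node pair.

    Interactions whose two anchors merged into the same node would be
    self-loops; they are dropped and counted in ``g.graph["n_self_loops"]``.
    """
    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        g.add_node(int(row.node_id), chrom=row.chrom, start=int(row.start),
                   end=int(row.end), classes=set(), gene_names=[],
                   lncrna_names=[], composite_label="unknown")
    n_self = 0
    for row in s.df.itertuples(index=False):
        u = anchor_to_node[(row.chrom_a, row.start_a, row.end_a)]
        v = anchor_to_node[(row.chrom_b, row.start_b, row.end_b)]
        if u == v:
            n_self += 1
            continue
        g.add_edge(u, v)
    g.graph["n_self_loops_dropped"] = n_self
    return g


def annotate_nodes(g: nx.Graph, tracks: list[pd.DataFrame]) -> nx.Graph:
    """Overlay annotation tracks onto graph nodes (in place; returns g).

    Strand-ignored >= 1 bp interval overlap; a node's class set is the
    union over all overlapping features; "repressed" is dropped; gene and
    lncRNA names accumulate (sorted, unique); nodes left with an empty
    class set are labeled "unknown".  Idempotent and monotone: re-running
    with the same tracks changes nothing, adding tracks never removes
    classes.
    """
    trees: dict[str, IntervalTree] = {}
    for track in tracks:
        bad = set(track["feature_class"]) - KNOWN_CLASSES
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")
        for row in track.itertuples(index=False):
            if row.start >= row.end:
                continue
            trees.setdefault(row.chrom, IntervalTree()).addi(
                row.start, row.end, (row.feature_class, row.name))

    for v, data in g.nodes(data=True):
        tree = trees.get(data["chrom"])
        if tree is None:
            hits = []
        else:
            hits = [iv.data for iv in tree.overlap(data["start"], data["end"])]
        classes = set(data.get("classes") or set())
        classes.discard("unknown")
        genes = set(data.get("gene_names") or [])
        lncs = set(data.get("lncrna_names") or [])
        for cls, name in hits:
            if cls == "repressed":
                continue
            classes.add(cls)
            if cls == "gene":
                genes.add(name)
            elif cls == "lncRNA":
                lncs.add(name)
        if not classes:
            classes = {"unknown"}
        data["classes"] = classes
        data["gene_names"] = sorted(genes)
        data["lncrna_names"] = sorted(lncs)
        data["composite_label"] = composite_label(classes)
    return g


def connected_components(g: nx.Graph) -> list[list]:
    """Connected components as node lists, largest first (ties broken by
    smallest member node id for determinism)."""
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0] if c else -1))
    return comps


def component_summary(g: nx.Graph) -> pd.DataFrame:
    """Per-chromosome component census: number of components and
    min/mean/max component size."""
    rows = []
    for chrom in sorted({d["chrom"] for _, d in g.nodes(data=True)}):
        sub = chromosome_subgraph(g, chrom)
        sizes = [len(c) for c in nx.connected_components(sub)]
        rows.append((chrom, len(sizes), min(sizes),
                     float(sum(sizes)) / len(sizes), max(sizes)))
    return pd.DataFrame(rows, columns=["chrom", "n_components", "min_size",
                                       "mean_size", "max_size"])


def chromosome_subgraph(g: nx.Graph, chrom: str) -> nx.Graph:
    """Induced subgraph on one chromosome's nodes."""
    nodes = [v for v, d in g.nodes(data=True) if d["chrom"] == chrom]
    if not nodes:
        raise KeyError(f"no nodes on chromosome {chrom!r}")
    return g.subgraph(nodes).copy()


def write_graph(g: nx.Graph, out_dir) -> dict:
    """Write nodes/edges TSVs; returns the path map."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    node_rows = []
    for v, d in sorted(g.nodes(data=True)):
        node_rows.append((v, d["chrom"], d["start"], d["end"],
                          d.get("composite_label", "unknown"),
                          ",".join(d.get("gene_names", [])),
                          ",".join(d.get("lncrna_names", []))))
    nodes_path = os.path.join(out_dir, "nodes.tsv")
    edges_path = os.path.join(out_dir, "edges.tsv")
    pd.DataFrame(node_rows, columns=["node_id", "chrom", "start", "end",
                                     "composite_label", "gene_names",
                                     "lncrna_names"]
                 ).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(sorted(tuple(sorted(e)) for e in g.edges),
                 columns=["node_id_a", "node_id_b"]
                 ).to_csv(edges_path, sep="\t", index=False)
    return {"nodes": nodes_path, "edges": edges_path}


def read_graph(graph_dir) -> nx.Graph:
    """Read a graph written by :func:`write_graph`."""
    import os
    nodes = pd.read_csv(os.path.join(graph_dir, "nodes.tsv"), sep="\t",
                        keep_default_na=False)
    edges = pd.read_csv(os.path.join(graph_dir, "edges.tsv"), sep="\t")
    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        label = row.composite_label or "unknown"
        # composite labels join multi-word classes with the same separator;
        # recover them against the canonical vocabulary
        classes = _parse_label(label)
        g.add_node(int(row.node_id), chrom=row.chrom, start=int(row.start),
                   end=int(row.end), classes=classes,
                   composite_label=label,
                   gene_names=[x for x in str(row.gene_names).split(",") if x],
                   lncrna_names=[x for x in str(row.lncrna_names).split(",") if x])
    for row in edges.itertuples(index=False):
        g.add_edge(int(row.node_id_a), int(row.node_id_b))
    return g


def _parse_label(label: str) -> set[str]:
    if label == "unknown":
        return {"unknown"}
    classes, rest = set(), label
    while rest:
        for cls in CLASS_ORDER:
            if rest == cls or rest.startswith(cls + "_"):
                classes.add(cls)
                rest = rest[len(cls) + 1:]
                break
        else:
            raise ValueError(f"cannot parse composite label {label!r}")
    return classes
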