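import itertools

import networkx as nx
import pytest

from chiamod import graph_build as gb
from chiamod.pet_filtering import InteractionSet


def _iset(records):
    return InteractionSet.from_records(records)


class TestMergeAnchors:
    def test_overlapping_anchors_union(self):
        s = _iset([("chr1", 100, 200, "chr1", 10_000, 10_100),
                   ("chr1", 150, 250, "chr1", 20_000, 20_100)])
        nodes, amap = gb.merge_anchors(s)
        merged = nodes[(nodes.start == 100) & (nodes.end == 250)]
        assert len(merged) == 1
        assert amap[("chr1", 100, 200)] == amap[("chr1", 150, 250)]

    def test_disjoint_anchors_distinct(self):
        s = _iset([("chr1", 0, 100, "chr1", 1000, 1100)])
        nodes, amap = gb.merge_anchors(s)
        assert len(nodes) == 2
        assert amap[("chr1", 0, 100)] != amap[("chr1", 1000, 1100)]

    def test_transitive_chain_merges(self):
        s = _iset([("chr1", 0, 10, "chr1", 10_000, 10_010),
                   ("chr1", 5, 15, "chr1", 20_000, 20_010),
                   ("chr1", 12, 20, "chr1", 30_000, 30_010)])
        nodes, amap = gb.merge_anchors(s)
        # transitive-closure interval-merge oracle
        keys = [("chr1", 0, 10), ("chr1", 5, 15), ("chr1", 12, 20)]
        assert len({amap[k] for k in keys}) == 1
        node = nodes[nodes.node_id == amap[keys[0]]].iloc[0]
        assert (node.start, node.end) == (0, 20)

    def test_adjacent_halfopen_anchors_do_not_merge(self):
        s = _iset([("chr1", 0, 10, "chr1", 10, 20)])
        nodes, _ = gb.merge_anchors(s)
        assert len(nodes) == 2

    def test_every_anchor_mapped(self, fixture_bundle):
        from chiamod.pet_filtering import read_interactions
        s = read_interactions(fixture_bundle["rep1"])
        _, amap = gb.merge_anchors(s)
        for r in s:
            assert (r.chrom_a, r.start_a, r.end_a) in amap
            assert (r.chrom_b, r.start_b, r.end_b) in amap


class TestBuildGraph:
    def test_path_of_interactions(self):
        coords = [(i * 1000, i * 1000 + 100) for i in range(4)]
        recs = [("chr1", *coords[i], "chr1", *coords[i + 1]) for i in range(3)]
        s = _iset(recs)
        nodes, amap = gb.merge_anchors(s)
        g = gb.build_graph(s, nodes, amap)
        assert nx.is_isomorphic(g, nx.path_graph(4))

    def test_merged_anchor_interaction_drops_self_loop(self):
        s = _iset([("chr1", 0, 100, "chr1", 50, 150)])
        nodes, amap = gb.merge_anchors(s)
        g = gb.build_graph(s, nodes, amap)
        assert g.number_of_edges() == 0
        assert g.graph["n_self_loops_dropped"] == 1

    def test_parallel_interactions_collapse(self):
        s = _iset([("chr1", 0, 100, "chr1", 1000, 1100),
                   ("chr1", 0, 100, "chr1", 1050, 1150)])
        nodes, amap = gb.merge_anchors(s)
        g = gb.build_graph(s, nodes, amap)
        assert g.number_of_edges() == 1


class TestAnnotateNodes:
    def _graph_one_node(self):
        g = nx.Graph()
        g.add_node(0, chrom="chr1", start=100, end=200, classes=set(),
                   gene_names=[], lncrna_names=[], composite_label="unknown")
        return g

    def test_lncrna_plus_enhancer_composite(self):
        g = self._graph_one_node()
        tracks = [gb.make_track([("chr1", 90, 150, "+", "lncRNA", "LNC1")]),
                  gb.make_track([("chr1", 150, 250, ".", "enhancer", "enh")])]
        gb.annotate_nodes(g, tracks)
        assert g.nodes[0]["composite_label"] == "lncRNA_enhancer"

    def test_repressed_only_is_unknown(self):
        g = self._graph_one_node()
        gb.annotate_nodes(g, [gb.make_track(
            [("chr1", 0, 500, ".", "repressed", "R")])])
        assert g.nodes[0]["classes"] == {"unknown"}
        assert g.nodes[0]["composite_label"] == "unknown"

    def test_two_genes_opposite_strands_both_names(self):
        g = self._graph_one_node()
        gb.annotate_nodes(g, [gb.make_track([
            ("chr1", 50, 150, "+", "gene", "GENEA"),
            ("chr1", 150, 300, "-", "gene", "GENEB")])])
        assert g.nodes[0]["gene_names"] == ["GENEA", "GENEB"]

    def test_no_overlap_stays_unknown(self):
        g = self._graph_one_node()
        gb.annotate_nodes(g, [gb.make_track(
            [("chr2", 0, 500, ".", "gene", "G")])])
        assert g.nodes[0]["composite_label"] == "unknown"

    def test_unknown_feature_class_rejected(self):
        with pytest.raises(ValueError):
            gb.make_track([("chr1", 0, 10, ".", "exon", "x")])

    def test_idempotent(self):
        g = self._graph_one_node()
        tracks = [gb.make_track([("chr1", 90, 150, "+", "lncRNA", "LNC1"),
                                 ("chr1", 150, 250, ".", "enhancer", "enh")])]
        gb.annotate_nodes(g, tracks)
        snapshot = {k: (set(v["classes"]), list(v["gene_names"]),
                        v["composite_label"]) for k, v in g.nodes(data=True)}
        gb.annotate_nodes(g, tracks)
        after = {k: (set(v["classes"]), list(v["gene_names"]),
                     v["composite_label"]) for k, v in g.nodes(data=True)}
        assert snapshot == after

    def test_adding_tracks_is_monotone(self):
        g = self._graph_one_node()
        gb.annotate_nodes(g, [gb.make_track(
            [("chr1", 90, 150, "+", "lncRNA", "LNC1")])])
        before = set(g.nodes[0]["classes"])
        gb.annotate_nodes(g, [gb.make_track(
            [("chr1", 150, 250, ".", "enhancer", "enh")])])
        assert before <= g.nodes[0]["classes"]


class TestComponents:
    def test_two_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        for v in g.nodes:
            g.nodes[v].update(chrom="chr1", start=v * 100, end=v * 100 + 50)
        comps = gb.connected_components(g)
        assert [len(c) for c in comps] == [3, 3]

    def test_empty_graph(self):
        assert gb.connected_components(nx.Graph()) == []

    def test_sizes_partition_nodes(self, planted_graph):
        g, _ = planted_graph
        comps = gb.connected_components(g)
        assert sum(len(c) for c in comps) == g.number_of_nodes()
        # maximality: no edge crosses components
        membership = {v: i for i, c in enumerate(comps) for v in c}
        assert all(membership[u] == membership[v] for u, v in g.edges)

    def test_p_out_zero_components_equal_plant(self):
        from chiamod.synthetic_data import PlantedNetworkSpec, gen_planted_graph
        g, labels = gen_planted_graph(
            PlantedNetworkSpec(module_sizes=(8, 8), p_in=1.0, p_out=0.0, seed=1))
        comps = gb.connected_components(g)
        got = [set(c) for c in comps]
        want = [{v for v in g.nodes if labels[v] == m} for m in (0, 1)]
        assert all(c in want for c in got)


class TestChromosomeSubgraph:
    def _two_chrom_graph(self):
        g = nx.Graph()
        for v in range(4):
            g.add_node(v, chrom="chr1" if v < 2 else "chr2",
                       start=v * 100, end=v * 100 + 50)
        g.add_edge(0, 1)
        g.add_edge(2, 3)
        return g

    def test_partition_and_edge_filter(self):
        g = self._two_chrom_graph()
        s1 = gb.chromosome_subgraph(g, "chr1")
        s2 = gb.chromosome_subgraph(g, "chr2")
        assert set(s1.nodes) | set(s2.nodes) == set(g.nodes)
        # brute-force: edges with both endpoints on the chromosome
        want = {e for e in g.edges if all(g.nodes[v]["chrom"] == "chr1" for v in e)}
        assert set(s1.edges) == want

    def test_single_chromosome_identity(self, planted_graph):
        g, _ = planted_graph
        sub = gb.chromosome_subgraph(g, "chr1")
        assert set(sub.nodes) == set(g.nodes)
        assert sub.number_of_edges() == g.number_of_edges()

    def test_unknown_chromosome_raises(self):
        with pytest.raises(KeyError):
            gb.chromosome_subgraph(self._two_chrom_graph(), "chrX")


class TestLabels:
    @pytest.mark.parametrize("classes, label", [
        ({"gene"}, "gene"),
        ({"enhancer", "lncRNA"}, "lncRNA_enhancer"),
        ({"transcribed", "CTCF", "gene"}, "gene_CTCF_transcribed"),
        (set(), "unknown"),
        ({"weak_enhancer", "promoter_flanking"},
         "weak_enhancer_promoter_flanking"),
    ])
    def test_composite_label_order(self, classes, label):
        assert gb.composite_label(classes) == label

    @pytest.mark.parametrize("classes", [
        {"gene"}, {"lncRNA", "enhancer"}, {"weak_enhancer", "TSS"},
        {"gene", "lncRNA", "CTCF", "transcribed"}, set()])
    def test_label_parse_roundtrip(self, classes):
        label = gb.composite_label(classes)
        assert gb._parse_label(label) == (classes or {"unknown"})


def test_graph_write_read_roundtrip(tmp_path, planted_graph):
    g, _ = planted_graph
    gb.write_graph(g, tmp_path)
    g2 = gb.read_graph(tmp_path)
    assert set(g2.nodes) == set(g.nodes)
    assert {tuple(sorted(e)) for e in g2.edges} == \
        {tuple(sorted(e)) for e in g.edges}
    for v in g.nodes:
        assert g2.nodes[v]["classes"] == g.nodes[v]["classes"]
        assert g2.nodes[v]["gene_names"] == g.nodes[v]["gene_names"]


def test_gtf_ingestion_converts_coordinates(tmp_path):
    gtf = tmp_path / "genes.gtf"
    gtf.write_text('chr1\thavana\tgene\t101\t200\t.\t+\t.\tgene_id "G1"; '
                   'gene_name "GENE1";\n'
                   'chr1\thavana\texon\t101\t150\t.\t+\t.\tgene_id "G1";\n')
    track = gb.read_gtf_track(gtf, "gene")
    assert len(track) == 1  # exon rows skipped
    row = track.iloc[0]
    assert (row["start"], row["end"], row["name"]) == (100, 200, "GENE1")
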