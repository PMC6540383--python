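import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from chiamod import msm_clustering as msm
from chiamod.synthetic_data import PlantedNetworkSpec, gen_planted_graph
from chiamod.validation import dense_committors, monte_carlo_affiliations
from conftest import random_connected_graph


class TestGenerator:
    def test_single_edge_closed_form(self):
        L, nodes = msm.build_generator(nx.path_graph(2))
        assert np.allclose(L.toarray(), [[-1, 1], [1, -1]])
        w = np.linalg.eigvalsh(L.toarray())
        assert np.allclose(sorted(w), [-2, 0], atol=1e-12)

    def test_triangle_matches_dense_eigensolver(self):
        L, _ = msm.build_generator(nx.complete_graph(3))
        dense = L.toarray()
        assert np.allclose(np.diag(dense), -2)
        w = np.sort(np.linalg.eigvalsh(dense))
        assert np.allclose(w, [-3, -3, 0], atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_row_sums_zero_and_symmetry(self, seed):
        g = random_connected_graph(15, 0.3, seed)
        L, _ = msm.build_generator(g)
        dense = L.toarray()
        assert np.allclose(dense.sum(axis=1), 0, atol=1e-12)
        assert np.allclose(dense, dense.T)

    def test_disconnected_rejected(self):
        g = nx.disjoint_union(nx.path_graph(2), nx.path_graph(2))
        with pytest.raises(ValueError):
            msm.build_generator(g)


class TestDominantSpectrum:
    def test_two_cliques_bridge_gap_after_two(self, two_cliques_bridge):
        L, _ = msm.build_generator(two_cliques_bridge)
        report = msm.dominant_spectrum(L, 6)
        w = report.eigenvalues
        assert w[0] == 0.0
        assert w[1] < 0.5          # slow bridge-crossing mode
        assert w[2] > 5            # bulk intra-clique modes
        assert report.gap_index == 2

    def test_complete_graph_spectrum(self):
        n = 8
        L, _ = msm.build_generator(nx.complete_graph(n))
        report = msm.dominant_spectrum(L, 5)
        assert report.eigenvalues[0] == 0.0
        assert np.allclose(report.eigenvalues[1:], n, atol=1e-9)

    def test_invariants_nonneg_and_sorted(self):
        g = random_connected_graph(30, 0.2, 3)
        L, _ = msm.build_generator(g)
        report = msm.dominant_spectrum(L, 8)
        assert report.eigenvalues[0] == 0.0
        assert (np.diff(report.eigenvalues) >= -1e-12).all()
        ts = report.implied_timescales[np.isfinite(report.implied_timescales)]
        assert (np.diff(ts) <= 1e-9).all()

    def test_sparse_path_matches_dense(self):
        g = random_connected_graph(msm._DENSE_LIMIT + 50, 0.01, 0)
        L, _ = msm.build_generator(g)
        sparse_report = msm.dominant_spectrum(L, 6)
        dense_w = np.sort(np.linalg.eigvalsh(-L.toarray()))[:6]
        dense_w[np.abs(dense_w) < 1e-10] = 0.0
        assert np.allclose(sparse_report.eigenvalues, dense_w, atol=1e-8)


class TestChooseNumModules:
    def test_alpha_limit_gives_single_module(self):
        report = msm.SpectrumReport(np.array([0.0, 0.1, 0.5]), np.eye(3),
                                    np.array([np.inf, 10.0, 2.0]), 1)
        assert msm.choose_num_modules(report, 1e12) == 1

    def test_direct_count(self):
        report = msm.SpectrumReport(np.array([0.0, 1e-4, 0.5]), np.eye(3),
                                    np.array([np.inf, 1e4, 2.0]), 2)
        assert msm.choose_num_modules(report, 1000) == 2

    def test_monotone_non_increasing_in_alpha(self, two_cliques_bridge):
        L, _ = msm.build_generator(two_cliques_bridge)
        report = msm.dominant_spectrum(L, 10)
        ms = [msm.choose_num_modules(report, a)
              for a in [1e6, 1e4, 100, 10, 1, 0.1]]
        assert all(m1 <= m2 for m1, m2 in zip(ms, ms[1:]))
        assert ms[0] == 1  # above the slowest timescale: no partition
        # inside the dominant gap the two metastable modules are selected
        assert msm.choose_num_modules(report, msm.suggest_alpha(report)) == 2


class TestIdentifyCores:
    def test_cores_inside_cliques_exclude_bridge(self, two_cliques_bridge):
        L, _ = msm.build_generator(two_cliques_bridge)
        report = msm.dominant_spectrum(L, 4)
        cores = msm.identify_cores(report.eigenvectors, 2, core_fraction=0.5,
                                   seed=0)
        flat = np.concatenate(cores)
        assert len(flat) == len(set(flat))
        sides = [set(c) for c in cores]
        assert any(s <= set(range(1, 10)) for s in sides)      # clique 1 sans bridge
        assert any(s <= set(range(11, 20)) for s in sides)     # clique 2 sans bridge
        assert 0 not in set(flat) and 10 not in set(flat)

    def test_seeded_determinism(self, two_cliques_bridge):
        L, _ = msm.build_generator(two_cliques_bridge)
        report = msm.dominant_spectrum(L, 4)
        a = msm.identify_cores(report.eigenvectors, 2, seed=5)
        b = msm.identify_cores(report.eigenvectors, 2, seed=5)
        assert all((x == y).all() for x, y in zip(a, b))


class TestCommittors:
    def test_path_midpoint_symmetry(self):
        L, _ = msm.build_generator(nx.path_graph(3))
        Q = msm.committor_affiliations(L, [np.array([0]), np.array([2])])
        assert Q[1, 0] == pytest.approx(0.5)

    def test_gamblers_ruin_on_path4(self):
        L, _ = msm.build_generator(nx.path_graph(4))
        Q = msm.committor_affiliations(L, [np.array([0]), np.array([3])])
        assert Q[1, 0] == pytest.approx(2 / 3)
        assert Q[2, 0] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_solve_and_monte_carlo(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(int(rng.integers(6, 15)), 0.35, seed)
        n = g.number_of_nodes()
        L, _ = msm.build_generator(g)
        perm = rng.permutation(n)
        cores = [np.array([perm[0]]), np.array([perm[1]])]
        Q = msm.committor_affiliations(L, cores)
        assert np.abs(Q - dense_committors(L, cores)).max() < 1e-10
        Qmc = monte_carlo_affiliations(L, cores, n_walks=20_000, seed=seed)
        assert np.abs(Q - Qmc).max() < 0.02
        assert np.abs(Q.sum(axis=1) - 1).max() < 1e-8
        assert Q.min() >= 0 and Q.max() <= 1

    def test_overlapping_cores_rejected(self):
        L, _ = msm.build_generator(nx.path_graph(4))
        with pytest.raises(ValueError):
            msm.committor_affiliations(L, [np.array([0, 1]), np.array([1, 3])])


class TestAssignModules:
    def test_theta_one_assigns_only_certain_nodes(self):
        Q = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        assignment, transition = msm.assign_modules(Q, 1.0)
        assert list(assignment) == [0, msm.UNASSIGNED, 1]
        assert list(transition) == [1]

    def test_balanced_node_unassigned_at_theta_07(self):
        L, _ = msm.build_generator(nx.path_graph(3))
        Q = msm.committor_affiliations(L, [np.array([0]), np.array([2])])
        assignment, transition = msm.assign_modules(Q, 0.7)
        assert assignment[1] == msm.UNASSIGNED

    def test_tie_at_half_goes_to_lowest_index(self):
        Q = np.array([[0.5, 0.5]])
        assignment, _ = msm.assign_modules(Q, 0.5)
        assert assignment[0] == 0

    def test_theta_monotonicity(self, planted_graph):
        g, _ = planted_graph
        comp = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        L, _ = msm.build_generator(comp)
        report = msm.dominant_spectrum(L, 8)
        cores = msm.identify_cores(report.eigenvectors, 3, seed=0)
        Q = msm.committor_affiliations(L, cores)
        assigned = {}
        for theta in (1.0, 0.7, 0.5):
            a, _ = msm.assign_modules(Q, theta)
            assigned[theta] = set(np.flatnonzero(a != msm.UNASSIGNED))
        assert assigned[1.0] <= assigned[0.7] <= assigned[0.5]


class TestClusterComponent:
    def test_planted_recovery_over_seeds(self):
        passes = 0
        for seed in range(10):
            g, _ = gen_planted_graph(PlantedNetworkSpec(seed=seed))
            comp = g.subgraph(max(nx.connected_components(g), key=len)).copy()
            L, _ = msm.build_generator(comp)
            alpha = msm.suggest_alpha(msm.dominant_spectrum(L, 10))
            clustering = msm.cluster_component(comp, alpha, 0.7, seed=seed)
            truth = np.array([g.nodes[v]["planted_module"]
                              for v in clustering.nodes])
            mask = clustering.assignment != msm.UNASSIGNED
            if adjusted_rand_score(truth[mask],
                                   clustering.assignment[mask]) >= 0.9:
                passes += 1
        assert passes >= 9

    def test_disconnected_limit_perfect_per_component(self):
        g, labels = gen_planted_graph(
            PlantedNetworkSpec(module_sizes=(25, 25), p_in=0.4, p_out=0.0,
                               seed=2))
        for comp_nodes in nx.connected_components(g):
            comp = g.subgraph(comp_nodes).copy()
            clustering = msm.cluster_component(comp, alpha=1.0, theta=0.7,
                                               seed=0)
            # a pure planted block is one metastable unit at any resolution
            planted = {labels[v] for v in clustering.nodes}
            assert len(planted) == 1
            assert clustering.m == 1
            assert len(clustering.transition_region) == 0

    def test_small_component_reported_whole(self):
        clustering = msm.cluster_component(nx.path_graph(5), 100, 0.7)
        assert clustering.m == 1
        assert (clustering.assignment == 0).all()

    def test_row_stochastic_affiliations(self, planted_graph):
        g, _ = planted_graph
        comp = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        clustering = msm.cluster_component(comp, alpha=3.0, theta=0.7, seed=1)
        assert clustering.m >= 2
        assert np.abs(clustering.Q.sum(axis=1) - 1).max() < 1e-8
        for i, core in enumerate(clustering.cores):
            assert np.allclose(clustering.Q[core, i], 1.0)

    def test_seeded_determinism(self, planted_graph):
        g, _ = planted_graph
        comp = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        a = msm.cluster_component(comp, 3.0, 0.7, seed=4)
        b = msm.cluster_component(comp, 3.0, 0.7, seed=4)
        assert (a.assignment == b.assignment).all()
        assert np.allclose(a.Q, b.Q)
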