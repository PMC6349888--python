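import math

import networkx as nx
import numpy as np
import pytest

from netstates.graphdist import (
    MEASURES,
    GraphMatrixBundle,
    deltacon_distance,
    density_matrix,
    edit_distance,
    jsd_distance,
    laplacian_spectrum,
    pairwise_distance_matrix,
    spectral_distance,
    von_neumann_entropy,
)
from netstates.snapshots import SnapshotSequence

from oracles import deltacon_reference, dense_laplacian_eigs


def snapshot_sequence(graphs, nodes):
    full = []
    for g in graphs:
        h = nx.Graph()
        h.add_nodes_from(nodes)
        h.add_edges_from(g.edges)
        full.append(h)
    return SnapshotSequence(tau=1.0, graphs=full, nodes=tuple(nodes),
                            per_window_event_count=np.zeros(len(full), dtype=int))


class TestEditDistance:
    def test_edge_difference_global_mode(self):
        g1 = nx.Graph([(1, 2)]); g1.add_node(3)
        g2 = nx.Graph([(1, 2), (2, 3)])
        assert edit_distance(g1, g2, "global") == 1

    def test_identical_graphs(self):
        g = nx.gnp_random_graph(8, 0.4, seed=1)
        assert edit_distance(g, g) == 0

    def test_disjoint_active_nodes(self):
        g1 = nx.Graph([(1, 2)])
        g2 = nx.Graph([(3, 4)])
        assert edit_distance(g1, g2, "active") == 6  # 2+2-0 nodes, 1+1-0 edges

    def test_weighted_input_rejected(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=2.0)
        with pytest.raises(ValueError, match="unweighted"):
            edit_distance(g, g)


class TestDeltacon:
    def test_matches_straight_line_reference(self, random_graph_pairs):
        for g1, g2 in random_graph_pairs[:8]:
            nodes = sorted(set(g1) | set(g2))
            A1 = nx.to_numpy_array(g1, nodelist=nodes)
            A2 = nx.to_numpy_array(g2, nodelist=nodes)
            expected = deltacon_reference(A1, A2)
            assert deltacon_distance(g1, g2, nodelist=nodes) == pytest.approx(expected, abs=1e-9)

    def test_three_node_example(self):
        g1 = nx.Graph([(1, 2)]); g1.add_node(3)
        g2 = nx.Graph([(1, 2), (2, 3)])
        nodes = [1, 2, 3]
        A1 = nx.to_numpy_array(g1, nodelist=nodes)
        A2 = nx.to_numpy_array(g2, nodelist=nodes)
        assert deltacon_distance(g1, g2) == pytest.approx(deltacon_reference(A1, A2))

    def test_identity_and_symmetry(self, random_graph_pairs):
        g1, g2 = random_graph_pairs[0]
        assert deltacon_distance(g1, g1) == 0.0
        assert deltacon_distance(g1, g2) == pytest.approx(deltacon_distance(g2, g1))


class TestLaplacianSpectrum:
    def test_single_edge_both_kinds(self):
        g = nx.Graph([(0, 1)])
        assert laplacian_spectrum(g, "combinatorial") == pytest.approx([0.0, 2.0])
        assert laplacian_spectrum(g, "normalised") == pytest.approx([0.0, 2.0])

    def test_empty_graph_all_zero(self):
        g = nx.empty_graph(5)
        for kind in ("combinatorial", "normalised"):
            assert laplacian_spectrum(g, kind) == pytest.approx(np.zeros(5))

    def test_matches_dense_eigendecomposition(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(2**31)))
            nodes = sorted(g)
            A = nx.to_numpy_array(g, nodelist=nodes)
            np.testing.assert_allclose(
                laplacian_spectrum(g, "combinatorial", nodes),
                dense_laplacian_eigs(A), atol=1e-8)
            np.testing.assert_allclose(
                laplacian_spectrum(g, "normalised", nodes),
                dense_laplacian_eigs(A, normalised=True), atol=1e-8)

    def test_isolates_contribute_zero_eigenvalues_normalised(self):
        g = nx.Graph([(0, 1)])
        g.add_nodes_from([2, 3, 4])
        spec = laplacian_spectrum(g, "normalised")
        assert np.sum(spec < 1e-12) == 4  # K2's zero + three isolates

    def test_normalised_eigenvalues_bounded_by_two(self, random_graph_pairs):
        for g, _ in random_graph_pairs:
            assert laplacian_spectrum(g, "normalised").max() <= 2 + 1e-9

    def test_combinatorial_extreme_eigenvalue_bounds(self, random_graph_pairs):
        # for any graph with an edge: d_max + 1 <= lambda_max <= 2 d_max
        for g, _ in random_graph_pairs:
            if g.number_of_edges() == 0:
                continue
            dmax = max(d for _, d in g.degree)
            lam = laplacian_spectrum(g, "combinatorial").max()
            assert dmax + 1 - 1e-8 <= lam <= 2 * dmax + 1e-8

    def test_directed_graph_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            laplacian_spectrum(nx.DiGraph([(0, 1)]))


class TestSpectralDistance:
    @pytest.mark.parametrize("kind", ["combinatorial", "normalised"])
    @pytest.mark.parametrize("variant", ["unnormalised", "normalised_distance"])
    def test_identity(self, kind, variant):
        g = nx.gnp_random_graph(10, 0.3, seed=3)
        assert spectral_distance(g, g, kind, variant) == 0.0

    def test_k2_versus_empty(self):
        g1 = nx.Graph([(0, 1)])
        g2 = nx.empty_graph(2)
        assert spectral_distance(g1, g2, "combinatorial", "unnormalised") == pytest.approx(2.0)
        assert spectral_distance(g1, g2, "combinatorial", "normalised_distance") == pytest.approx(1.0)

    def test_both_empty_normalised_distance_zero(self):
        assert spectral_distance(nx.empty_graph(3), nx.empty_graph(3),
                                 "combinatorial", "normalised_distance") == 0.0

    def test_permutation_invariance(self, rng):
        g = nx.gnp_random_graph(12, 0.3, seed=9)
        perm = dict(zip(g.nodes, rng.permutation(list(g.nodes))))
        h = nx.relabel_nodes(g, {k: int(v) for k, v in perm.items()})
        for kind in ("combinatorial", "normalised"):
            assert spectral_distance(g, h, kind, "unnormalised") == pytest.approx(0.0, abs=1e-8)

    def test_unequal_node_counts_rejected(self):
        with pytest.raises(ValueError, match="equal node counts"):
            spectral_distance(nx.empty_graph(3), nx.empty_graph(4))

    def test_normalised_distance_bounded_by_sqrt2(self, random_graph_pairs):
        for g1, g2 in random_graph_pairs:
            for kind in ("combinatorial", "normalised"):
                d = spectral_distance(g1, g2, kind, "normalised_distance")
                assert d <= math.sqrt(2) + 1e-9

    def test_n_eig_out_of_range(self):
        g = nx.empty_graph(4)
        with pytest.raises(ValueError, match="n_eig"):
            spectral_distance(g, g, n_eig=5)


class TestJensenShannon:
    def test_identity(self):
        g = nx.gnp_random_graph(8, 0.4, seed=5)
        assert jsd_distance(g, g) == pytest.approx(0.0, abs=1e-7)

    def test_two_node_closed_form(self):
        # rho for the empty 2-node graph is I/2; for K2 the eigenvalues
        # are {1, e^-2}/(1+e^-2); the mixture diagonalises in the
        # {(1,1),(1,-1)}/sqrt(2) basis shared by both density matrices
        p = 1.0 / (1.0 + math.exp(-2.0))
        H = lambda q: -q * math.log2(q) - (1 - q) * math.log2(1 - q)
        mix1, mix2 = 0.25 + p / 2, 0.25 + (1 - p) / 2
        s_mix = -(mix1 * math.log2(mix1) + mix2 * math.log2(mix2))
        expected = math.sqrt(s_mix - (1.0 + H(p)) / 2)
        got = jsd_distance(nx.empty_graph(2), nx.Graph([(0, 1)]), beta=1.0)
        assert got == pytest.approx(expected, abs=1e-10)
        assert got == pytest.approx(0.3594, abs=5e-4)

    def test_entropy_limits(self):
        assert von_neumann_entropy(np.eye(4) / 4) == pytest.approx(2.0)
        pure = np.zeros((4, 4)); pure[0, 0] = 1.0
        assert von_neumann_entropy(pure) == pytest.approx(0.0)

    @pytest.mark.parametrize("beta", [0.1, 1.0, 10.0])
    def test_density_matrix_unit_trace(self, beta, random_graph_pairs):
        for g, _ in random_graph_pairs[:5]:
            rho = density_matrix(g, beta=beta)
            assert abs(np.trace(rho) - 1.0) < 1e-12
            assert np.linalg.eigvalsh(rho).min() > -1e-12

    def test_distance_in_unit_interval(self, random_graph_pairs):
        for g1, g2 in random_graph_pairs[:8]:
            assert 0.0 <= jsd_distance(g1, g2) <= 1.0 + 1e-9

    def test_invariant_under_joint_relabelling(self, rng):
        # relabelling both graphs by the same permutation conjugates both
        # density matrices identically, leaving the divergence unchanged
        g1 = nx.gnp_random_graph(10, 0.3, seed=11)
        g2 = nx.gnp_random_graph(10, 0.3, seed=12)
        perm = {i: int(v) for i, v in enumerate(rng.permutation(10))}
        h1, h2 = nx.relabel_nodes(g1, perm), nx.relabel_nodes(g2, perm)
        assert jsd_distance(h1, h2) == pytest.approx(jsd_distance(g1, g2), abs=1e-8)

    def test_nonpositive_beta_rejected(self):
        g = nx.empty_graph(2)
        with pytest.raises(ValueError, match="beta"):
            jsd_distance(g, g, beta=0.0)


class TestMeasureAxioms:
    """d(G,G)=0, symmetry and nonnegativity for all seven measures."""

    @pytest.mark.parametrize("measure", MEASURES)
    def test_identity_symmetry_nonnegativity(self, measure, random_graph_pairs):
        from netstates.graphdist import _pair_measure

        fn = _pair_measure(measure, {})
        for g1, g2 in random_graph_pairs[:6]:
            nodes = sorted(set(g1) | set(g2))
            assert abs(fn(g1, g1, nodes)) <= 1e-9
            d12, d21 = fn(g1, g2, nodes), fn(g2, g1, nodes)
            assert d12 == pytest.approx(d21, abs=1e-9)
            assert d12 >= 0

    def test_edit_distance_not_permutation_invariant(self):
        g = nx.path_graph(6)
        h = nx.relabel_nodes(g, {i: (i + 1) % 6 for i in range(6)})
        assert edit_distance(g, h) > 0


class TestPairwiseMatrix:
    def test_identical_snapshots_all_zero(self):
        g = nx.gnp_random_graph(6, 0.5, seed=2)
        snaps = snapshot_sequence([g, g, g], sorted(g))
        for measure in ("edit", "nlap_normalized", "jsd"):
            D = pairwise_distance_matrix(snaps, measure)
            assert np.allclose(D.d, 0.0, atol=1e-7)

    @pytest.mark.parametrize("measure", MEASURES)
    def test_matches_per_pair_calls(self, measure, rng):
        from netstates.graphdist import _pair_measure

        graphs = [nx.gnp_random_graph(8, 0.35, seed=int(rng.integers(2**31)))
                  for _ in range(5)]
        nodes = list(range(8))
        snaps = snapshot_sequence(graphs, nodes)
        D = pairwise_distance_matrix(snaps, measure)
        assert np.array_equal(D.d, D.d.T)
        assert np.all(np.diag(D.d) == 0)
        fn = _pair_measure(measure, {})
        for i in range(5):
            for j in range(i + 1, 5):
                assert D.d[i, j] == pytest.approx(
                    fn(snaps.graphs[i], snaps.graphs[j], list(snaps.nodes)), abs=1e-9)

    def test_unknown_measure_lists_options(self):
        g = nx.empty_graph(3)
        snaps = snapshot_sequence([g, g], range(3))
        with pytest.raises(ValueError, match="edit"):
            pairwise_distance_matrix(snaps, "nope")


def test_bundle_laplacian_row_sums_zero(random_graph_pairs):
    for g, _ in random_graph_pairs[:5]:
        b = GraphMatrixBundle.from_graph(g)
        np.testing.assert_allclose(b.L.sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(b.Lnorm, b.Lnorm.T, atol=1e-12)
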