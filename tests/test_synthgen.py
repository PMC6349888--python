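import networkx as nx
import numpy as np
import pytest
from scipy.stats import ks_2samp, spearmanr

from netstates.snapshots import bin_events
from netstates.synthgen import (
    BASpec,
    LFRSpec,
    PlantedTemporalSpec,
    RRGSpec,
    barabasi_albert,
    lfr_benchmark,
    model_distance_experiment,
    planted_temporal_network,
    realized_mixing,
    regular_random_graph,
    sample_graph,
)


class TestRegularRandomGraph:
    def test_every_degree_equals_k(self):
        g = regular_random_graph(RRGSpec(n=100, k=6), seed=0)
        assert {d for _, d in g.degree} == {6}
        assert g.number_of_nodes() == 100

    def test_k1_is_perfect_matching(self):
        g = regular_random_graph(RRGSpec(n=4, k=1), seed=0)
        assert g.number_of_edges() == 2
        assert {d for _, d in g.degree} == {1}

    def test_deterministic_in_seed(self):
        e1 = set(regular_random_graph(RRGSpec(), seed=7).edges)
        e2 = set(regular_random_graph(RRGSpec(), seed=7).edges)
        assert e1 == e2

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            RRGSpec(n=5, k=5)
        with pytest.raises(ValueError):
            RRGSpec(n=5, k=3)  # odd n*k


class TestBarabasiAlbert:
    def test_exact_edge_count_and_min_degree(self):
        g = barabasi_albert(BASpec(n=100, m0=3, m=3), seed=0)
        assert g.number_of_edges() == 3 + 3 * 97  # clique + m per arrival
        assert min(d for _, d in g.degree) == 3
        assert 2 * g.number_of_edges() / 100 == pytest.approx(5.88)

    def test_deterministic_in_seed(self):
        assert set(barabasi_albert(BASpec(), seed=3).edges) == set(
            barabasi_albert(BASpec(), seed=3).edges)

    def test_degree_uncorrelated_with_node_index(self):
        # labels are randomly permuted, so across seeds the rank
        # correlation between index and degree averages to zero
        corrs = []
        for seed in range(100):
            g = barabasi_albert(BASpec(), seed=seed)
            degs = [g.degree(i) for i in range(100)]
            corrs.append(spearmanr(range(100), degs).statistic)
        assert abs(np.mean(corrs)) < 0.05

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BASpec(n=10, m0=2, m=3)


class TestLFR:
    def test_realized_mixing_close_to_mu(self):
        mixes = [realized_mixing(lfr_benchmark(LFRSpec(mu=0.1), seed=s))
                 for s in range(20)]
        assert abs(np.mean(mixes) - 0.1) < 0.05

    def test_max_degree_bounded(self):
        for s in range(5):
            g = lfr_benchmark(LFRSpec(mu=0.3), seed=s)
            assert max(d for _, d in g.degree) <= 25

    def test_degree_distribution_independent_of_mu(self):
        pooled = {}
        for mu in (0.1, 0.9):
            degs = []
            for s in range(10):
                g = lfr_benchmark(LFRSpec(mu=mu), seed=s)
                degs.extend(d for _, d in g.degree)
            pooled[mu] = degs
        assert ks_2samp(pooled[0.1], pooled[0.9]).pvalue > 0.01

    def test_every_node_has_community(self):
        g = lfr_benchmark(LFRSpec(mu=0.2), seed=1)
        communities = nx.get_node_attributes(g, "community")
        assert set(communities) == set(g.nodes)

    def test_deterministic_in_seed(self):
        assert set(lfr_benchmark(LFRSpec(), seed=5).edges) == set(
            lfr_benchmark(LFRSpec(), seed=5).edges)

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError, match="mu"):
            LFRSpec(mu=1.0)


class TestModelDistanceExperiment:
    def test_between_mean_normalised_to_one(self):
        df = model_distance_experiment(
            RRGSpec(), BASpec(), n_pairs=10,
            measures="lap_unnormalized", seed=0)
        assert df.loc[("lap_unnormalized", "AB"), "mean_norm"] == 1.0

    def test_rrg_ba_separation_with_spectral_distance(self):
        df = model_distance_experiment(
            RRGSpec(), BASpec(), n_pairs=30,
            measures="lap_unnormalized", seed=1)
        ab = df.loc[("lap_unnormalized", "AB")]
        for comp in ("AA", "BB"):
            row = df.loc[("lap_unnormalized", comp)]
            assert ab["mean"] > row["mean"] + row["sd"]

    def test_sampling_consistency_across_n_pairs(self):
        small = model_distance_experiment(RRGSpec(), BASpec(), n_pairs=50,
                                          measures="lap_unnormalized", seed=2)
        large = model_distance_experiment(RRGSpec(), BASpec(), n_pairs=200,
                                          measures="lap_unnormalized", seed=3)
        for comp in ("AA", "BB", "AB"):
            s, l = small.loc[("lap_unnormalized", comp)], large.loc[("lap_unnormalized", comp)]
            se = np.hypot(s["sd"] / np.sqrt(50), l["sd"] / np.sqrt(200))
            assert abs(s["mean"] - l["mean"]) < 3 * se

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError, match="unknown measure"):
            model_distance_experiment(RRGSpec(), BASpec(), n_pairs=2,
                                      measures="nope")


class TestPlantedTemporalNetwork:
    def test_binning_round_trips_window_edge_sets(self):
        spec = PlantedTemporalSpec(
            states=(1, 2, 1), models={1: RRGSpec(n=20, k=4), 2: BASpec(n=20)},
            tau=5.0, seed=11)
        rng = np.random.default_rng(11)
        expected = []
        for t, s in enumerate(spec.states):
            g = sample_graph(spec.models[s], int(rng.integers(2**31)))
            expected.append({frozenset(e) for e in g.edges})
            for _ in g.edges:
                rng.random()  # event-time draws interleave with graph seeds
        events, labels = planted_temporal_network(spec)
        snaps = bin_events(events, 5.0, drop_partial=False)
        assert snaps.t_max == 3
        got = [{frozenset(e) for e in g.edges} for g in snaps.graphs]
        assert got == expected
        assert list(labels) == [1, 2, 1]

    def test_constant_state_sequence_single_model(self):
        spec = PlantedTemporalSpec(
            states=(1, 1, 1), models={1: RRGSpec(n=10, k=2)}, tau=1.0, seed=0)
        events, _ = planted_temporal_network(spec)
        snaps = bin_events(events, 1.0, drop_partial=False)
        for g in snaps.graphs:
            assert {d for _, d in g.degree if d > 0} <= {2}

    def test_deterministic_in_seed(self):
        spec = PlantedTemporalSpec(
            states=(1, 2), models={1: RRGSpec(n=10, k=2), 2: BASpec(n=10, m0=2, m=2)},
            tau=1.0, seed=4)
        e1, _ = planted_temporal_network(spec)
        e2, _ = planted_temporal_network(spec)
        assert [(e.time, e.u, e.v) for e in e1.events] == [
            (e.time, e.u, e.v) for e in e2.events]

    def test_missing_model_rejected(self):
        with pytest.raises(ValueError, match="without a model"):
            PlantedTemporalSpec(states=(1, 2), models={1: RRGSpec()})
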