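"""Spearman statistics, thresholded network construction, hubs and incidence."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from ffnet import (
    AssociationNetwork,
    FeatureAnnotation,
    NetworkConfig,
    ValidationError,
    build_bipartite,
    build_cooccurrence,
    cooccurrence_incidence,
    find_hubs,
    spearman_pvalue,
    spearman_rho,
    split_by_sign,
)
from conftest import make_table


class TestSpearmanRho:
    def test_monotone_pair(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0

    def test_antitone_pair(self):
        assert spearman_rho([1, 2, 3, 4], [40, 30, 20, 10]) == -1.0

    def test_tie_aware_hand_value(self):
        # ranks of y are (1.5, 1.5, 3.5, 3.5); Pearson with (1,2,3,4) = 2/sqrt(5)
        assert spearman_rho([1, 2, 3, 4], [1, 1, 2, 2]) == pytest.approx(
            2 / math.sqrt(5), abs=1e-12
        )

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.random(6), rng.random(6)
            assert spearman_rho(x, y) == pytest.approx(spearman_rho(y, x), abs=1e-15)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_scipy_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            x = rng.integers(0, 5, size=8).astype(float)
            y = rng.integers(0, 5, size=8).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            ref = scipy.stats.spearmanr(x, y).statistic
            assert spearman_rho(x, y) == pytest.approx(ref, abs=1e-12)


class TestSpearmanPvalue:
    def test_zero_rho_gives_one(self):
        assert spearman_pvalue(0.0, 10, "asymptotic_t") == pytest.approx(1.0)

    def test_perfect_rho_asymptotic_is_zero(self):
        assert spearman_pvalue(1.0, 4, "asymptotic_t") == 0.0

    def test_perfect_rho_exact_n4(self):
        # only the identity and the reversal of 4 ranks reach |rho| = 1
        assert spearman_pvalue(1.0, 4, "exact_permutation") == pytest.approx(2 / 24)

    def test_exact_matches_enumeration_oracle(self):
        for n in (4, 5):
            base = list(range(1, n + 1))
            rhos = sorted(
                {
                    round(scipy.stats.pearsonr(base, p).statistic, 12)
                    for p in itertools.permutations(base)
                }
            )
            perms = list(itertools.permutations(base))
            for rho in rhos:
                tail = sum(
                    1
                    for p in perms
                    if abs(scipy.stats.pearsonr(base, p).statistic) >= abs(rho) - 1e-9
                )
                expected = tail / len(perms)
                assert spearman_pvalue(rho, n, "exact_permutation") == pytest.approx(
                    expected, abs=1e-12
                )

    def test_monte_carlo_beyond_enumeration_limit(self):
        p = spearman_pvalue(0.5, 12, "exact_permutation", mc_permutations=5000)
        asym = spearman_pvalue(0.5, 12, "asymptotic_t")
        assert 0 < p < 1 and abs(p - asym) < 0.05


def _tables_from_rows(rows, mode="raw", prefix="F"):
    return make_table(rows, mode=mode,
                      features=[f"{prefix}{i + 1}" for i in range(len(rows))])


class TestBipartite:
    def test_noise_free_recovery_matches_planted_truth(self, noise_free_dataset):
        ds = noise_free_dataset
        net = build_bipartite(ds.microbe_table, ds.volatile_table)
        found = net.edge_pairs()
        truth = {tuple(sorted((m, v))) for m, v, _ in ds.truth_edges}
        assert found == truth
        # planted signs are recovered too
        sign_of = {tuple(sorted((m, v))): s for m, v, s in ds.truth_edges}
        for e in net.edges:
            assert e.sign == sign_of[tuple(sorted((e.feature_a, e.feature_b)))]

    def test_no_within_role_edges(self, noise_free_dataset):
        ds = noise_free_dataset
        net = build_bipartite(ds.microbe_table, ds.volatile_table)
        roles = nx.get_node_attributes(net.graph, "role")
        for u, v in net.graph.edges():
            assert {roles[u], roles[v]} == {"microbe", "volatile"}

    def test_impossible_threshold_gives_empty_network(self):
        # strict |rho| > 0.999999 requires perfect monotonicity, which has
        # probability ~0 for continuous random profiles
        rng = np.random.default_rng(5)
        microbes = _tables_from_rows(rng.random((5, 8)), prefix="M")
        volatiles = _tables_from_rows(rng.random((6, 8)), prefix="V")
        cfg = NetworkConfig(rho_threshold=0.999999)
        net = build_bipartite(microbes, volatiles, cfg)
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_constant_row_skipped_with_warning(self):
        microbes = _tables_from_rows([[1, 1, 1, 1], [1, 2, 3, 4]], prefix="M")
        volatiles = _tables_from_rows([[4, 3, 2, 1]], prefix="V")
        with pytest.warns(UserWarning, match="constant"):
            net = build_bipartite(microbes, volatiles)
        assert "M1" not in net.graph

    def test_sample_mismatch_errors(self):
        microbes = _tables_from_rows([[1, 2, 3]], prefix="M")
        volatiles = make_table([[1, 2, 3]], features=["V1"], samples=["a", "b", "c"])
        with pytest.raises(ValidationError, match="sample"):
            build_bipartite(microbes, volatiles)

    def test_threshold_monotonicity(self, noisy_dataset):
        ds = noisy_dataset
        loose = build_bipartite(ds.microbe_table, ds.volatile_table,
                                NetworkConfig(rho_threshold=0.6, alpha=0.05))
        tight_rho = build_bipartite(ds.microbe_table, ds.volatile_table,
                                    NetworkConfig(rho_threshold=0.8, alpha=0.05))
        tight_alpha = build_bipartite(ds.microbe_table, ds.volatile_table,
                                      NetworkConfig(rho_threshold=0.6, alpha=0.01))
        assert tight_rho.edge_pairs() <= loose.edge_pairs()
        assert tight_alpha.edge_pairs() <= loose.edge_pairs()

    def test_row_permutation_invariance(self, noisy_dataset):
        ds = noisy_dataset
        net = build_bipartite(ds.microbe_table, ds.volatile_table)
        perm = np.random.default_rng(0).permutation(ds.microbe_table.n_features)
        shuffled = make_table(
            ds.microbe_table.values[perm], mode="relative",
            features=[ds.microbe_table.feature_ids[i] for i in perm],
            samples=ds.microbe_table.sample_ids,
        )
        net2 = build_bipartite(shuffled, ds.volatile_table)
        assert net.edge_pairs() == net2.edge_pairs()


class TestCooccurrence:
    def test_covarying_pair_gives_positive_edge(self):
        t = _tables_from_rows([[1, 2, 3, 4], [2, 4, 6, 8]])
        net = build_cooccurrence(t)
        assert net.n_edges == 1
        assert net.edges[0].sign == 1

    def test_mirrored_pair_gives_negative_edge(self):
        t = _tables_from_rows([[1, 2, 3, 4], [8, 6, 4, 2]])
        net = build_cooccurrence(t)
        assert net.n_edges == 1
        assert net.edges[0].sign == -1

    @pytest.mark.parametrize("k", [3, 5])
    def test_rank_identical_taxa_form_complete_graph(self, k):
        rows = [np.arange(1.0, 5.0) * (i + 1) for i in range(k)]
        net = build_cooccurrence(_tables_from_rows(rows))
        assert net.n_edges == k * (k - 1) // 2
        assert all(e.sign == 1 for e in net.edges)

    def test_no_self_edges(self, noisy_dataset):
        net = build_cooccurrence(noisy_dataset.microbe_table)
        assert all(u != v for u, v in net.graph.edges())


class TestSplitBySign:
    def test_all_positive_toy(self):
        net = build_cooccurrence(_tables_from_rows([[1, 2, 3, 4], [2, 4, 6, 8]]))
        pos, neg = split_by_sign(net)
        assert pos.n_edges == 1 and neg.n_edges == 0 and neg.n_nodes == 0

    def test_partition_conserves_edge_count(self, noisy_dataset):
        net = build_bipartite(noisy_dataset.microbe_table, noisy_dataset.volatile_table)
        pos, neg = split_by_sign(net)
        assert pos.n_edges + neg.n_edges == net.n_edges
        assert pos.edge_pairs() | neg.edge_pairs() == net.edge_pairs()
        assert not pos.edge_pairs() & neg.edge_pairs()

    def test_mixed_toy_counts_match_hand_partition(self):
        # 3 rank-identical rising taxa (3 positive edges) + 2 falling taxa:
        # falling pair is mutually positive, and each falling-rising pair negative
        rows = [
            [1, 2, 3, 4], [2, 3, 4, 5], [1, 3, 5, 7],
            [9, 7, 5, 3], [8, 6, 4, 2],
        ]
        net = build_cooccurrence(_tables_from_rows(rows))
        pos, neg = split_by_sign(net)
        assert pos.n_edges == 4
        assert neg.n_edges == 6


class TestHubs:
    def _star(self, n_leaves):
        g = nx.Graph()
        for i in range(n_leaves):
            g.add_edge("hub", f"leaf{i}", rho=0.9, p=0.01, sign=1)
        return AssociationNetwork(g, bipartite=False)

    def test_star_with_ten_leaves(self):
        assert find_hubs(self._star(10), min_degree=10) == ["hub"]

    def test_star_with_nine_leaves(self):
        assert find_hubs(self._star(9), min_degree=10) == []

    def test_three_hub_toy_sorted_by_degree_then_id(self):
        g = nx.Graph()
        for hub, n in (("b", 12), ("a", 12), ("c", 10)):
            for i in range(n):
                g.add_edge(hub, f"{hub}_leaf{i}", rho=0.9, p=0.01, sign=1)
        net = AssociationNetwork(g, bipartite=False)
        assert find_hubs(net, min_degree=10) == ["a", "b", "c"]


class TestIncidence:
    def _annots(self):
        return [
            FeatureAnnotation("m1", "microbe", phylum="Firmicutes"),
            FeatureAnnotation("m2", "microbe", phylum="Proteobacteria"),
            FeatureAnnotation("m3", "microbe", phylum="Firmicutes"),
            FeatureAnnotation("m4", "microbe", phylum="Ascomycota"),
        ]

    def _net(self, edges):
        g = nx.Graph()
        for u, v in edges:
            g.add_edge(u, v, rho=0.9, p=0.01, sign=1)
        return AssociationNetwork(g, bipartite=False)

    def test_hand_enumerated_fractions(self):
        net = self._net([("m1", "m2"), ("m1", "m3"), ("m2", "m4")])
        inc = cooccurrence_incidence(net, self._annots())
        assert inc.fraction_cross_phylum == pytest.approx(2 / 3)
        assert inc.fraction_within_phylum == pytest.approx(1 / 3)
        assert inc.pair_fractions[("Firmicutes", "Proteobacteria")] == pytest.approx(1 / 3)
        assert sum(inc.pair_fractions.values()) == pytest.approx(1.0)

    def test_all_within_one_phylum(self):
        net = self._net([("m1", "m3")])
        inc = cooccurrence_incidence(net, self._annots())
        assert inc.fraction_within_phylum == 1.0

    def test_empty_network_errors(self):
        with pytest.raises(ValidationError, match="no edges"):
            cooccurrence_incidence(self._net([]), self._annots())

    def test_missing_phylum_errors(self):
        net = self._net([("m1", "m9")])
        with pytest.raises(ValidationError, match="m9"):
            cooccurrence_incidence(net, self._annots())


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=15, deadline=None, derandomize=True)
def test_rho_matrix_agrees_with_pairwise_rho(seed):
    rng = np.random.default_rng(seed)
    microbes = _tables_from_rows(rng.random((3, 6)), prefix="M")
    volatiles = _tables_from_rows(rng.random((3, 6)), prefix="V")
    net = build_bipartite(microbes, volatiles, NetworkConfig(rho_threshold=0.6))
    for e in net.edges:
        # undirected edges carry no endpoint-role order
        m, v = sorted((e.feature_a, e.feature_b))  # M* sorts before V*
        direct = spearman_rho(microbes.data.loc[m], volatiles.data.loc[v])
        assert e.rho == pytest.approx(direct, abs=1e-12)
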