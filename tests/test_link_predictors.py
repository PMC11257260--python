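"""The 9 link predictors: exact values, oracles, and ranking behavior."""

import math

import numpy as np
import pytest

from missnet.graph_core import Graph, canonical_edge
from missnet.link_predictors import (
    FAMILIES,
    FAMILY,
    FEATURE_NAMES,
    PATH_LENGTH_CAP,
    PredictorSpec,
    extract_pair_features,
    fit_block_model,
    score_block_density,
    score_local,
    score_node2vec,
    score_pairs,
    score_spectral,
    score_topstacking,
)
from missnet.missingness_samplers import SamplerSpec
from missnet.protocol import make_split_bundle, sample_graph
from missnet.synthetic_networks import generate_planted_partition


def brute_force_local(adj, u, v, index):
    """Independent oracle: explicit neighbor-set arithmetic."""
    nu, nv = adj[u], adj[v]
    cn = nu & nv
    if index == "adamic_adar":
        return sum(1.0 / math.log(len(adj[z])) for z in cn)
    if index == "jaccard":
        return len(cn) / len(nu | nv) if (nu | nv) else 0.0
    return len(nu) * len(nv)


def _all_nonadjacent_pairs(g):
    nodes = sorted(g.nodes)
    return [
        (u, v)
        for i, u in enumerate(nodes)
        for v in nodes[i + 1 :]
        if not g.has_edge(u, v)
    ]


def two_clique_bundle(seed=0, clique=10):
    """Two dense cliques; bundle built with a uniform-edge sampler."""
    edges = [(i, j) for i in range(clique) for j in range(i + 1, clique)]
    edges += [(i, j) for i in range(clique, 2 * clique) for j in range(i + 1, 2 * clique)]
    # three bridges keep both cliques in the LCC after the test split
    edges += [(0, clique), (1, clique + 1), (2, clique + 2)]
    g = Graph.from_edges(edges)
    bundle = make_split_bundle(g, SamplerSpec("random_edge", seed=seed), seed)
    return g, bundle, sample_graph(bundle)


class TestRegistry:
    def test_nine_predictors_four_families(self):
        assert len(FAMILY) == 9
        assert set(FAMILY.values()) == set(FAMILIES) and len(FAMILIES) == 4


class TestLocalIndices:
    def test_path_adamic_adar(self, path3):
        t = score_local(path3, [(0, 2)], "adamic_adar")
        assert t[(0, 2)] == pytest.approx(1.0 / math.log(2))

    def test_cycle_jaccard_is_one(self, cycle4):
        assert score_local(cycle4, [(0, 2)], "jaccard")[(0, 2)] == 1.0

    def test_star_leaf_pair(self, star4):
        pairs = [(1, 2)]
        assert score_local(star4, pairs, "preferential_attachment")[(1, 2)] == 1.0
        assert score_local(star4, pairs, "jaccard")[(1, 2)] == 1.0

    def test_disconnected_pair_scores_zero(self):
        g = Graph.from_edges([(0, 1), (2, 3)])
        for index in ("adamic_adar", "jaccard", "preferential_attachment"):
            # no common neighbors; PA = 1*1 but J and AA are 0
            t = score_local(g, [(0, 2)], index)
            if index == "preferential_attachment":
                assert t[(0, 2)] == 1.0
            else:
                assert t[(0, 2)] == 0.0

    @pytest.mark.parametrize("index", ["adamic_adar", "jaccard", "preferential_attachment"])
    def test_matches_brute_force_on_random_graphs(self, index, random_graph_factory):
        for seed in range(50):
            n = int(10 + seed % 20)
            g = random_graph_factory(n, n + 10, seed=seed)
            adj = g.adjacency()
            nodes = sorted(g.nodes)
            pairs = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
            t = score_local(g, pairs, index)
            for u, v in pairs:
                assert t[(u, v)] == pytest.approx(brute_force_local(adj, u, v, index))

    def test_symmetry(self, random_graph_factory):
        g = random_graph_factory(12, 25, seed=1)
        t = score_local(g, [(3, 7)], "adamic_adar")
        assert t[(3, 7)] == t[(7, 3)]

    def test_sentinel_for_absent_endpoint(self, path3):
        t = score_local(path3, [(0, 2), (0, 99)], "adamic_adar")
        assert t[(0, 99)] == min(t.entries.values())


class TestSpectral:
    def test_separates_cliques_and_probability_range(self):
        g, bundle, sample = two_clique_bundle(seed=1)
        pairs = _all_nonadjacent_pairs(sample)
        t = score_spectral(sample, bundle, pairs, seed=1, class_size=500, cv=False)
        within = [t[p] for p in pairs if (p[0] < 10) == (p[1] < 10)]
        between = [t[p] for p in pairs if (p[0] < 10) != (p[1] < 10)]
        assert all(0.0 <= s <= 1.0 for s in t.entries.values())
        if within and between:
            assert np.mean(within) > np.mean(between)

    def test_sentinel_for_absent_endpoint(self):
        g, bundle, sample = two_clique_bundle(seed=2)
        u = min(sample.nodes)
        t = score_spectral(
            sample, bundle, [(u, 999), (u, max(sample.nodes))],
            seed=0, class_size=200, cv=False,
        )
        assert t[(u, 999)] == min(t.entries.values())


class TestNode2Vec:
    def test_dot_product_identity(self):
        # inner product of identical vectors is the squared norm
        e = np.array([0.3, -1.2, 0.5])
        assert float(e @ e) == pytest.approx(np.linalg.norm(e) ** 2)

    @pytest.mark.parametrize("variant", ["dot", "edge_embedding"])
    def test_separates_cliques(self, variant):
        ok = 0
        for seed in range(5):
            g, bundle, sample = two_clique_bundle(seed=seed)
            pairs = _all_nonadjacent_pairs(sample)
            t = score_node2vec(
                sample, bundle, pairs, variant=variant,
                walks_per_node=5, walk_length=20, epochs=2,
                seed=seed, class_size=300, cv=False,
            )
            within = [t[p] for p in pairs if (p[0] < 10) == (p[1] < 10)]
            between = [t[p] for p in pairs if (p[0] < 10) != (p[1] < 10)]
            if variant == "edge_embedding":
                assert all(0.0 <= s <= 1.0 for s in t.entries.values())
            ok += np.mean(within) > np.mean(between)
        assert ok >= 4

    def test_deterministic_under_seed(self):
        g, bundle, sample = two_clique_bundle(seed=3)
        pairs = _all_nonadjacent_pairs(sample)[:5]
        kw = dict(variant="dot", walks_per_node=3, walk_length=10, epochs=1, seed=7)
        t1 = score_node2vec(sample, bundle, pairs, **kw)
        t2 = score_node2vec(sample, bundle, pairs, **kw)
        assert t1.entries == t2.entries


class TestBlockModels:
    def test_two_cliques_modularity_densities(self, two_cliques):
        labels, density = fit_block_model(two_cliques, "modularity", seed=0)
        assert len(set(labels.values())) == 2
        blocks = sorted(set(labels.values()))
        r, s = blocks
        assert density[(r, r)] == 1.0 and density[(s, s)] == 1.0
        assert density[(r, s)] == 0.0

    def test_single_block_density_matches_graph_density(self):
        g = Graph.from_edges([(0, 1), (1, 2), (2, 3), (0, 2)])
        labels = {u: 0 for u in g.nodes}
        from missnet.link_predictors import _block_stats

        _, sizes, m_rs, _ = _block_stats(g, labels)
        assert m_rs[(0, 0)] / math.comb(sizes[0], 2) == pytest.approx(
            g.m / math.comb(g.n, 2)
        )

    def test_densities_bounded_and_sizes_conserved(self, random_graph_factory):
        g = random_graph_factory(30, 70, seed=3)
        labels, density = fit_block_model(g, "modularity", seed=0)
        assert all(0.0 <= d <= 1.0 for d in density.values())
        assert len(labels) == g.n

    @pytest.mark.parametrize("model", ["modularity", "mdl_dcsbm"])
    def test_planted_partition_recovery_ranking(self, model):
        wins = 0
        for seed in range(5):
            g, truth = generate_planted_partition(120, 4, 0.5, 0.02, seed)
            lab = dict(enumerate(truth))
            pairs = _all_nonadjacent_pairs(g)[:400]
            t = score_block_density(g, pairs, model, seed)
            w = np.mean([t[p] for p in pairs if lab[p[0]] == lab[p[1]]])
            b = np.mean([t[p] for p in pairs if lab[p[0]] != lab[p[1]]])
            wins += w > b
        assert wins >= 4

    def test_same_block_pairs_share_scores(self, two_cliques):
        pairs = _all_nonadjacent_pairs(two_cliques)
        t = score_block_density(two_cliques, pairs, "modularity", 0)
        within = {t[p] for p in pairs if (p[0] < 5) == (p[1] < 5)}
        assert len(within) <= 1  # constant density within one block pair


class TestPairFeatures:
    def test_hand_enumerated_path(self, path3):
        X = extract_pair_features(path3, [(0, 2)])
        row = dict(zip(FEATURE_NAMES, X[0]))
        assert row["degree_u"] == 1 and row["degree_v"] == 1
        assert row["common_neighbors"] == 1
        assert row["adamic_adar"] == pytest.approx(1 / math.log(2))
        assert row["jaccard"] == 1.0
        assert row["shortest_path_capped"] == 2

    def test_sentinel_vector(self, path3):
        X = extract_pair_features(path3, [(0, 99)])
        row = dict(zip(FEATURE_NAMES, X[0]))
        assert row["shortest_path_capped"] == PATH_LENGTH_CAP
        assert sum(v for k, v in row.items() if k != "shortest_path_capped") == 0.0

    def test_constant_feature_length(self, random_graph_factory):
        g = random_graph_factory(15, 30, seed=2)
        X = extract_pair_features(g, [(0, 1), (2, 14), (0, 999)])
        assert X.shape == (3, len(FEATURE_NAMES))


class TestTopStacking:
    def test_scores_are_probabilities_and_no_leakage(self):
        g, bundle, sample = two_clique_bundle(seed=4)
        pairs = _all_nonadjacent_pairs(sample)[:30]
        t = score_topstacking(
            sample, bundle, pairs, seed=0, class_size=300,
            n_estimators=30, cv=False,
        )
        assert all(0.0 <= s <= 1.0 for s in t.entries.values())
        assert len(t.entries) == len({canonical_edge(*p) for p in pairs})

    def test_empty_validation_set_errors(self):
        g = Graph.from_edges([(i, i + 1) for i in range(8)] + [(0, 5)])
        bundle = make_split_bundle(g, SamplerSpec("random_edge", seed=0), 0)
        bundle_empty = type(bundle)(
            **{**bundle.__dict__, "Z": frozenset(),
               "E_sample": bundle.E_sample | bundle.Z}
        )
        with pytest.raises(ValueError, match="Z is empty"):
            score_topstacking(sample_graph(bundle_empty), bundle_empty, [(0, 7)])


class TestDispatcher:
    def test_every_registered_name_scores(self):
        g, bundle, sample = two_clique_bundle(seed=5)
        pairs = _all_nonadjacent_pairs(sample)[:10]
        fast = {
            "spectral": {"class_size": 200, "cv": False},
            "node2vec_dot": {"walks_per_node": 3, "walk_length": 10, "epochs": 1},
            "node2vec_edge": {
                "walks_per_node": 3, "walk_length": 10, "epochs": 1,
                "class_size": 200, "cv": False,
            },
            "top_stacking": {"class_size": 200, "n_estimators": 20, "cv": False},
        }
        for name in FAMILY:
            t = score_pairs(
                PredictorSpec(name, fast.get(name, {}), seed=1), sample, bundle, pairs
            )
            assert set(t.entries) == {canonical_edge(*p) for p in pairs}
            assert all(np.isfinite(list(t.entries.values())))
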