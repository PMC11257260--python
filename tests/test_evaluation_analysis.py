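"""AUC statistic, experiment matrix, aggregation, winners, and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from missnet.evaluation_analysis import (
    ResultRecord,
    aggregate_by_domain,
    compute_auc,
    count_best_methods,
    pca_sampler_profiles,
    records_to_frame,
    run_experiment,
)
from missnet.link_predictors import PredictorSpec, ScoreTable
from missnet.missingness_samplers import SamplerSpec
from missnet.synthetic_networks import generate_planted_partition


def brute_force_auc(pos, neg):
    """Oracle: count all pos-neg comparisons directly."""
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestComputeAUC:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_all_ties_half(self):
        assert compute_auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_partial_overlap(self):
        assert compute_auc([0.9, 0.4], [0.6, 0.1]) == 0.75

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            compute_auc([], [0.1])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.choice([0.1, 0.25, 0.5, 0.9], size=rng.integers(1, 200))
        neg = rng.choice([0.1, 0.25, 0.5, 0.9], size=rng.integers(1, 200))
        assert compute_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_complement_identity_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(50) / 50.0
        pos, neg = scores[:20], scores[20:]
        assert compute_auc(pos, neg) + compute_auc(neg, pos) == pytest.approx(1.0)


def oracle_scorer(sample, bundle, pairs, seed):
    """Reference predictor: 1 for true test edges, 0 otherwise."""
    return ScoreTable({p: (1.0 if p in bundle.Y else 0.0) for p in pairs}, "oracle")


def random_scorer(sample, bundle, pairs, seed):
    rng = np.random.default_rng(seed)
    return ScoreTable({p: float(rng.random()) for p in pairs}, "random")


@pytest.fixture(scope="module")
def small_networks():
    nets = []
    for i, dom in enumerate(["social", "biological"]):
        g, _ = generate_planted_partition(60, 3, 0.35, 0.05, seed=i)
        nets.append((f"{dom}_{i}", g, dom))
    return nets


class TestRunExperiment:
    def test_matrix_cardinality(self, small_networks):
        records, failures = run_experiment(
            small_networks[:1],
            [SamplerSpec("random_edge"), SamplerSpec("dfs")],
            [PredictorSpec("adamic_adar"), PredictorSpec("jaccard"),
             PredictorSpec("preferential_attachment")],
            repeats=2, master_seed=0, class_size=200,
        )
        assert len(records) + len(failures) == 12

    def test_deterministic_under_master_seed(self, small_networks):
        kw = dict(
            networks=small_networks[:1],
            samplers=[SamplerSpec("random_walk")],
            predictors=[PredictorSpec("adamic_adar")],
            repeats=2, master_seed=42, class_size=200,
        )
        r1, _ = run_experiment(**kw)
        r2, _ = run_experiment(**kw)
        assert [(r.auc, r.achieved_sample_size) for r in r1] == [
            (r.auc, r.achieved_sample_size) for r in r2
        ]

    def test_oracle_predictor_gets_perfect_auc(self, small_networks):
        records, failures = run_experiment(
            small_networks,
            [SamplerSpec("random_edge")],
            [PredictorSpec("oracle")],
            repeats=2, master_seed=1, class_size=500,
            custom_scorers={"oracle": oracle_scorer},
        )
        assert not failures
        assert all(r.auc == 1.0 for r in records)

    def test_auc_bounds_enforced(self):
        with pytest.raises(ValueError):
            ResultRecord("x", "social", "dfs", "jaccard", 0, 1.2, 10)


class TestAggregation:
    def _records(self):
        return [
            ResultRecord("n1", "social", "dfs", "jaccard", 0, 0.6, 10),
            ResultRecord("n1", "social", "dfs", "jaccard", 1, 0.8, 10),
            ResultRecord("n1", "social", "dfs", "adamic_adar", 0, 0.9, 10),
        ]

    def test_mean_and_population_sd(self):
        agg = aggregate_by_domain(self._records())
        row = agg[agg.predictor == "jaccard"].iloc[0]
        assert row.mean_auc == pytest.approx(0.7)
        assert row.sd_auc == pytest.approx(0.1)  # ddof=0 convention

    def test_single_record_sd_zero(self):
        agg = aggregate_by_domain(self._records())
        row = agg[agg.predictor == "adamic_adar"].iloc[0]
        assert row.mean_auc == 0.9 and row.sd_auc == 0.0

    def test_cell_count(self):
        recs = [
            ResultRecord("n1", d, s, p, 0, 0.5, 1)
            for d in ("social", "economic")
            for s in ("dfs", "random_edge")
            for p in ("jaccard",)
        ]
        assert len(aggregate_by_domain(recs)) == 4


class TestWinners:
    def test_unique_max(self):
        agg = pd.DataFrame(
            dict(domain=["d"] * 2, sampler=["s"] * 2,
                 predictor=["a", "b"], mean_auc=[0.9, 0.7])
        )
        assert count_best_methods(agg) == {"a": 1, "b": 0}

    def test_exact_tie_shares_win(self):
        agg = pd.DataFrame(
            dict(domain=["d"] * 3, sampler=["s"] * 3,
                 predictor=["a", "b", "c"], mean_auc=[0.8, 0.8, 0.1])
        )
        wins = count_best_methods(agg)
        assert wins == {"a": 1, "b": 1, "c": 0}

    def test_every_cell_awards_at_least_one_win(self):
        agg = pd.DataFrame(
            dict(domain=["d1", "d1", "d2", "d2"], sampler=["s", "s", "s", "s"],
                 predictor=["a", "b"] * 2, mean_auc=[0.6, 0.5, 0.4, 0.7])
        )
        assert sum(count_best_methods(agg).values()) >= 2


class TestPCA:
    def _records(self, vectors, samplers=None):
        samplers = samplers or [f"s{i}" for i in range(len(vectors))]
        recs = []
        for s, vec in zip(samplers, vectors):
            for j, auc in enumerate(vec):
                recs.append(ResultRecord(f"net{j}", "social", s, "jaccard", 0, auc, 1))
        return recs

    def test_identical_vectors_identical_scores(self):
        profiles = pca_sampler_profiles(
            self._records([[0.5, 0.6, 0.7]] * 2 + [[0.9, 0.2, 0.4]]),
            "social", "jaccard",
        )
        by_name = {p.sampler: p.pc_scores for p in profiles}
        assert by_name["s0"] == pytest.approx(by_name["s1"])

    def test_variance_ordering(self):
        rng = np.random.default_rng(0)
        vecs = rng.random((6, 5)).tolist()
        profiles = pca_sampler_profiles(self._records(vecs), "social", "jaccard")
        scores = np.array([p.pc_scores for p in profiles])
        assert scores[:, 0].var() >= scores[:, 1].var() >= 0

    def test_collinear_vectors_rank_one(self):
        # rank-1 data: second component vanishes
        base = np.array([0.2, 0.5, 0.9])
        vecs = [(0.1 + 0.3 * t) * base for t in range(4)]
        profiles = pca_sampler_profiles(
            self._records([v.tolist() for v in vecs]), "social", "jaccard"
        )
        for p in profiles:
            assert abs(p.pc_scores[1]) < 1e-9

    def test_too_few_samplers_errors(self):
        with pytest.raises(ValueError):
            pca_sampler_profiles(self._records([[0.5, 0.5]] * 2), "social", "jaccard")

    def test_result_frame_columns(self):
        df = records_to_frame(self._records([[0.5, 0.5]] * 3))
        assert list(df.columns) == [
            "network_id", "domain", "sampler", "predictor",
            "run_index", "auc", "achieved_sample_size",
        ]
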