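import logging

import numpy as np
import pytest

from conftest import random_interactions
from nbcfdti import (
    CVFold,
    DataError,
    InteractionMatrix,
    ScoreMatrix,
    SyntheticSpec,
    generate,
    make_folds,
    mpr,
    percentile_ranks,
    random_scorer,
    run_experiment,
)


def _dense_network(rng, m, n, min_degree):
    """Random matrix where every node has degree >= min_degree."""
    while True:
        mat = random_interactions(rng, m, n, density=0.4)
        if mat.drug_degrees().min() >= min_degree and mat.target_degrees().min() >= min_degree:
            return mat


class TestMakeFolds:
    def test_folds_partition_the_link_set(self):
        rng = np.random.default_rng(0)
        full = _dense_network(rng, 20, 15, min_degree=2)
        folds = make_folds(full, k=10, seed=1)
        all_test = [p for f in folds for p in f.test_pairs]
        assert len(all_test) == len(set(all_test))
        links = set(zip(*np.nonzero(full.values)))
        assert set(all_test) <= links

    def test_test_links_zeroed_in_train(self):
        rng = np.random.default_rng(1)
        full = _dense_network(rng, 15, 12, min_degree=2)
        for fold in make_folds(full, k=5, seed=2):
            for i, j in fold.test_pairs:
                assert full.values[i, j] == 1
                assert fold.train.values[i, j] == 0

    def test_degree_constraint_holds_in_every_fold(self):
        rng = np.random.default_rng(2)
        full = _dense_network(rng, 15, 12, min_degree=2)
        for fold in make_folds(full, k=10, seed=3):
            assert fold.train.drug_degrees().min() >= 1
            assert fold.train.target_degrees().min() >= 1

    def test_unconstrained_network_partitions_all_links(self):
        # every node has degree >= k, so no link is pinned
        full = InteractionMatrix(
            np.ones((6, 6), dtype=int),
            tuple(f"T{i}" for i in range(6)),
            tuple(f"D{j}" for j in range(6)),
        )
        folds = make_folds(full, k=3, seed=4)
        assert sum(len(f.test_pairs) for f in folds) == 36
        sizes = [len(f.test_pairs) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_fold_sizes_near_equal(self):
        rng = np.random.default_rng(5)
        full = _dense_network(rng, 25, 20, min_degree=3)
        folds = make_folds(full, k=10, seed=6)
        sizes = [len(f.test_pairs) for f in folds]
        assert max(sizes) - min(sizes) <= 2

    def test_star_network_pins_all_links(self, caplog):
        # one drug; every target has degree 1, so no link can ever be tested
        full = InteractionMatrix(
            np.ones((5, 1), dtype=int), tuple(f"T{i}" for i in range(5)), ("D0",)
        )
        with caplog.at_level(logging.WARNING, logger="nbcfdti"):
            folds = make_folds(full, k=2, seed=7)
        assert all(f.test_pairs == () for f in folds)
        assert any("pinned" in r.message for r in caplog.records)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(8)
        full = _dense_network(rng, 15, 12, min_degree=2)
        a = make_folds(full, k=5, seed=9)
        b = make_folds(full, k=5, seed=9)
        assert [f.test_pairs for f in a] == [f.test_pairs for f in b]

    def test_too_many_folds_rejected(self, toy):
        with pytest.raises(DataError, match="exceed"):
            make_folds(toy, k=50, seed=0)


def _fold_with(scores_shape, test_pairs):
    m, n = scores_shape
    values = np.zeros((m, n), dtype=int)
    full = InteractionMatrix(
        values, tuple(f"T{i}" for i in range(m)), tuple(f"D{j}" for j in range(n))
    )
    return CVFold(train=full, test_pairs=tuple(test_pairs), fold_id=0, seed=0)


class TestPercentileRanks:
    def test_strict_top_hit_ranks_zero(self):
        fold = _fold_with((1, 5), [(0, 2)])
        scores = ScoreMatrix(np.array([[0.1, 0.2, 0.9, 0.3, 0.0]]), "s1", "cosine")
        assert percentile_ranks(scores, fold)[(0, 2)] == 0.0

    def test_strict_bottom_hit_ranks_one(self):
        fold = _fold_with((1, 5), [(0, 4)])
        scores = ScoreMatrix(np.array([[0.1, 0.2, 0.9, 0.3, 0.0]]), "s1", "cosine")
        assert percentile_ranks(scores, fold)[(0, 4)] == 1.0

    def test_all_tied_scores_rank_half_under_average_rule(self):
        fold = _fold_with((1, 7), [(0, 3)])
        scores = ScoreMatrix(np.full((1, 7), 2.5), "s1", "cosine")
        assert percentile_ranks(scores, fold)[(0, 3)] == pytest.approx(0.5)

    def test_min_tie_rule_ranks_tied_pairs_top(self):
        fold = _fold_with((1, 4), [(0, 1)])
        scores = ScoreMatrix(np.full((1, 4), 1.0), "s1", "cosine")
        assert percentile_ranks(scores, fold, tie_rule="min")[(0, 1)] == 0.0

    def test_single_drug_rank_defined_zero(self):
        fold = _fold_with((2, 1), [(0, 0)])
        scores = ScoreMatrix(np.zeros((2, 1)), "s1", "cosine")
        assert percentile_ranks(scores, fold)[(0, 0)] == 0.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        fold = _fold_with((4, 9), [(0, 1), (1, 4), (3, 8)])
        raw = rng.random((4, 9))
        r1 = percentile_ranks(ScoreMatrix(raw, "s1", "c"), fold)
        r2 = percentile_ranks(ScoreMatrix(np.exp(3 * raw), "s1", "c"), fold)
        assert r1 == r2

    def test_reversing_scores_flips_ranks(self):
        rng = np.random.default_rng(11)
        fold = _fold_with((3, 8), [(0, 2), (2, 5)])
        raw = rng.random((3, 8))  # continuous, no ties
        r1 = percentile_ranks(ScoreMatrix(raw, "s1", "c"), fold)
        r2 = percentile_ranks(ScoreMatrix(-raw, "s1", "c"), fold)
        for pair in r1:
            assert r1[pair] + r2[pair] == pytest.approx(1.0)


class TestMPR:
    def test_single_top_ranked_pair_gives_zero(self):
        fold = _fold_with((1, 5), [(0, 2)])
        report = mpr({(0, 2): 0.0}, fold)
        assert report.mpr == 0.0 and report.n_test_targets == 1

    def test_mean_of_per_target_means(self):
        fold = _fold_with((3, 5), [(0, 1), (0, 3), (2, 0)])
        # R_0 = mean(0.1, 0.3) = 0.2, R_2 = 0.4 -> MPR = 0.3
        report = mpr({(0, 1): 0.1, (0, 3): 0.3, (2, 0): 0.4}, fold)
        assert report.mpr == pytest.approx(0.3)
        assert dict(report.per_target) == pytest.approx({0: 0.2, 2: 0.4})

    def test_empty_test_set_rejected(self):
        fold = _fold_with((2, 2), [])
        with pytest.raises(DataError, match="no test pairs"):
            mpr({}, fold)

    def test_rank_coverage_enforced(self):
        fold = _fold_with((2, 3), [(0, 1), (1, 2)])
        with pytest.raises(DataError, match="cover"):
            mpr({(0, 1): 0.5}, fold)


class TestRunExperiment:
    def test_reproducible_summary(self):
        rng = np.random.default_rng(12)
        full = _dense_network(rng, 20, 15, min_degree=2)
        a = run_experiment(full, metric="cosine", n_trials=2, k=5, seeds=[3, 4])
        b = run_experiment(full, metric="cosine", n_trials=2, k=5, seeds=[3, 4])
        assert a.trial_mprs == b.trial_mprs
        assert a.fold_mprs == b.fold_mprs

    def test_mpr_within_unit_interval_and_sd_reported(self):
        rng = np.random.default_rng(13)
        full = _dense_network(rng, 20, 15, min_degree=2)
        summary = run_experiment(full, metric="ppmi", n_trials=3, k=5, seeds=[1, 2, 3])
        assert 0.0 <= summary.mpr_mean <= 1.0
        assert summary.mpr_sd >= 0.0
        assert len(summary.trial_mprs) == 3

    def test_random_scores_give_mpr_near_half(self):
        matrix, _aux, _truth = generate(
            SyntheticSpec(n_targets=150, n_drugs=100, target_sparsity=0.02, seed=5)
        )
        summary = run_experiment(
            matrix, scorer=random_scorer, n_trials=5, k=10, seeds=[1, 2, 3, 4, 5]
        )
        assert summary.mpr_mean == pytest.approx(0.5, abs=0.03)

    def test_planted_structure_beats_random_with_margin(self):
        matrix, _aux, _truth = generate(
            SyntheticSpec(n_targets=200, n_drugs=150, target_sparsity=0.02,
                          within_block_boost=20.0, seed=3)
        )
        model = run_experiment(matrix, strategy="s1", metric="ppmi",
                               n_trials=2, k=10, seeds=[1, 2])
        baseline = run_experiment(matrix, scorer=random_scorer,
                                  n_trials=2, k=10, seeds=[1, 2])
        assert baseline.mpr_mean - model.mpr_mean > 0.1

    def test_seed_count_must_match_trials(self, toy):
        with pytest.raises(DataError, match="seeds"):
            run_experiment(toy, n_trials=3, seeds=[1])


def test_mpr_boxplot_writes_figure(tmp_path):
    from nbcfdti import mpr_boxplot

    rng = np.random.default_rng(20)
    full = _dense_network(rng, 20, 15, min_degree=2)
    summary = run_experiment(full, metric="cosine", n_trials=2, k=5, seeds=[1, 2])
    out = tmp_path / "mpr.png"
    mpr_boxplot({"s1/cosine": summary}, str(out))
    assert out.stat().st_size > 0
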