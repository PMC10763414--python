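"""Acquisition strategies: hand-worked selections, closed forms, oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

import lossgate as lg
from lossgate.samplers import bald_scores, topk_by_predicted_loss


def make_thresholds(vals):
    b = np.array([1.0 if v is None else v for v in vals], float)
    b[[v is None for v in vals]] = np.nan
    return lg.make_thresholds(b, 1.0)


class TestProposedSampler:
    def test_filter_then_topk_by_hand(self):
        ids = ["a", "b", "c", "d"]
        cls = [0, 0, 0, 0]
        lhat = [0.9, 0.5, 0.4, 0.1]
        ts = make_thresholds([0.8, 99.0, 99.0])
        sel = lg.propose_filtered_topk(ids, cls, lhat, ts, budget=2)
        assert set(sel.chosen_ids) == {"b", "c"}  # 0.9 filtered; top-2 of the rest

    def test_no_gate_reduces_to_learning_loss(self):
        rng = np.random.default_rng(0)
        ids = [f"p{i}" for i in range(30)]
        cls = rng.integers(0, 3, 30)
        lhat = rng.uniform(0, 5, 30)
        ts = make_thresholds([np.inf, np.inf, np.inf])
        gated = lg.propose_filtered_topk(ids, cls, lhat, ts, 9)
        ll = lg.learning_loss_sampler(ids, cls, lhat, 9)
        assert gated.chosen_ids == ll.chosen_ids

    def test_undefined_class_fails_open(self):
        ids = ["a", "b"]
        cls = [0, 1]
        lhat = [5.0, 5.0]
        ts = make_thresholds([None, 0.1, 0.1])  # class 0 undefined
        sel = lg.propose_filtered_topk(ids, cls, lhat, ts, 2)
        assert "a" in sel.chosen_ids  # class-0 candidate not filtered
        assert "b" not in sel.chosen_ids  # class-1 candidate gated

    def test_all_filtered_signals_empty(self):
        ts = make_thresholds([0.01, 0.01, 0.01])
        sel = lg.propose_filtered_topk(["a", "b"], [0, 1], [1.0, 1.0], ts, 2)
        assert sel.empty

    def test_equal_per_class_quota_with_reallocation(self):
        # 2 class-0 survivors, 6 class-1, budget 6: base quota 2 each, class 2
        # empty, its share goes to the richest remaining survivors
        ids = [f"p{i}" for i in range(8)]
        cls = [0, 0, 1, 1, 1, 1, 1, 1]
        lhat = [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3]
        sel = lg.learning_loss_sampler(ids, cls, lhat, 6)
        assert len(sel.chosen_ids) == 6
        assert {"p0", "p1"} <= set(sel.chosen_ids)  # both class-0 survivors
        # remaining 4 are the top class-1 losses
        assert set(sel.chosen_ids) - {"p0", "p1"} == {"p2", "p3", "p4", "p5"}


class TestEq6Optimality:
    def test_global_topk_matches_brute_force_subset_maximization(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            n = int(rng.integers(5, 13))
            k = int(rng.integers(1, n))
            ids = [f"p{i}" for i in range(n)]
            lhat = rng.normal(size=n)
            chosen = set(topk_by_predicted_loss(ids, lhat, k))
            best = max(
                itertools.combinations(range(n), k),
                key=lambda sub: sum(lhat[list(sub)]),
            )
            assert chosen == {ids[i] for i in best}


class TestLeastConfidence:
    def test_picks_lowest_max_probability(self):
        scores = np.log(np.array([[0.40, 0.35, 0.25], [0.95, 0.03, 0.02]]))
        sel = lg.least_confidence(["x", "y"], scores, 1)
        assert sel.chosen_ids == ("x",)

    def test_uniform_scores_tie_break_by_id(self):
        scores = np.zeros((4, 3))
        sel = lg.least_confidence(["d", "a", "c", "b"], scores, 2)
        assert sel.chosen_ids == ("a", "b")

    def test_budget_covers_pool(self):
        sel = lg.least_confidence(["a", "b"], np.zeros((2, 3)), 5)
        assert set(sel.chosen_ids) == {"a", "b"}


class TestEntropy:
    def test_closed_forms(self):
        logits = np.log(np.array([[1 / 3, 1 / 3, 1 / 3], [1.0, 1e-30, 1e-30], [0.5, 0.5, 1e-30]]))
        sel = lg.entropy_sampler(["u", "o", "h"], logits, 3)
        assert sel.scores["u"] == pytest.approx(np.log(3), abs=1e-9)
        assert sel.scores["o"] == pytest.approx(0.0, abs=1e-6)
        assert sel.scores["h"] == pytest.approx(np.log(2), abs=1e-6)
        assert sel.chosen_ids[0] == "u" and sel.chosen_ids[-1] == "o"

    def test_matches_least_confidence_on_binary_problems(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=(20, 2))
        ids = [f"p{i}" for i in range(20)]
        assert (
            lg.entropy_sampler(ids, scores, 7).chosen_ids
            == lg.least_confidence(ids, scores, 7).chosen_ids
        )


class TestBald:
    def test_identical_passes_zero_information(self):
        p = np.tile(np.array([[0.7, 0.2, 0.1]]), (5, 4, 1))
        np.testing.assert_allclose(bald_scores(p), 0.0, atol=1e-12)

    def test_two_disagreeing_onehot_passes(self):
        stack = np.array([[[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]])
        assert bald_scores(stack)[0] == pytest.approx(np.log(2))

    def test_scores_nonnegative(self):
        rng = np.random.default_rng(12)
        raw = rng.dirichlet(np.ones(3), size=(10, 6))
        assert np.all(bald_scores(raw) >= -1e-12)

    def test_too_few_passes_rejected(self):
        with pytest.raises(ValueError):
            bald_scores(np.ones((1, 2, 3)) / 3)


class TestCoreset:
    def test_farthest_point_first(self):
        sel = lg.coreset_kgreedy(["a", "b", "c"], [[0.0], [1.0], [10.0]], [[0.0]], 1)
        assert sel.chosen_ids == ("c",)

    def test_greedy_trace_budget_two(self):
        sel = lg.coreset_kgreedy(["a", "b", "c"], [[0.0], [1.0], [10.0]], [[0.0]], 2)
        assert sel.chosen_ids == ("c", "b")

    def test_two_approximation_of_optimal_cover(self):
        rng = np.random.default_rng(23)
        pts = rng.uniform(size=(20, 2))
        ids = [f"p{i:02d}" for i in range(20)]
        k = 3
        sel = lg.coreset_kgreedy(ids, pts, np.empty((0, 2)), k)
        centers = [ids.index(i) for i in sel.chosen_ids]
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        greedy_radius = d[:, centers].min(axis=1).max()
        opt = min(
            d[:, list(sub)].min(axis=1).max()
            for sub in itertools.combinations(range(20), k)
        )
        assert greedy_radius <= 2 * opt + 1e-12


class TestRandom:
    def test_seeded_repeatable(self):
        ids = [f"p{i}" for i in range(50)]
        a = lg.random_sampler(ids, 10, 42)
        b = lg.random_sampler(ids, 10, 42)
        assert a.chosen_ids == b.chosen_ids

    def test_budget_equals_pool(self):
        ids = ["a", "b", "c"]
        assert set(lg.random_sampler(ids, 3, 0).chosen_ids) == set(ids)

    def test_uniformity_chi_square(self):
        ids = [f"p{i}" for i in range(20)]
        counts = {i: 0 for i in ids}
        for seed in range(400):
            for i in lg.random_sampler(ids, 5, seed).chosen_ids:
                counts[i] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01


class TestPermutationInvariance:
    @pytest.mark.parametrize("which", ["proposed", "lc", "entropy"])
    def test_pool_order_irrelevant_with_distinct_scores(self, which):
        rng = np.random.default_rng(31)
        n = 25
        ids = [f"p{i}" for i in range(n)]
        cls = rng.integers(0, 3, n)
        lhat = rng.uniform(0, 4, n)
        scores = rng.normal(size=(n, 3))
        perm = rng.permutation(n)

        def select(order):
            oid = [ids[i] for i in order]
            if which == "proposed":
                ts = make_thresholds([2.0, 2.0, 2.0])
                return lg.propose_filtered_topk(
                    oid, cls[order], lhat[order], ts, 8
                ).chosen_ids
            if which == "lc":
                return lg.least_confidence(oid, scores[order], 8).chosen_ids
            return lg.entropy_sampler(oid, scores[order], 8).chosen_ids

        assert select(np.arange(n)) == select(perm)
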