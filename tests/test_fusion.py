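"""Binarization, fusion strategies, fold plans and metrics."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microfusion.classifiers import ProbabilityPair
from microfusion.fusion import (
    ConfusionCounts,
    FusionWeights,
    MetricSet,
    average_metrics,
    binarize_rating,
    confusion_and_metrics,
    fusion_grid_size,
    majority_vote,
    make_folds,
    search_fusion_weights,
    weighted_fusion,
)


class TestBinarize:
    @pytest.mark.parametrize("rating,expected", [(7, 1), (3, 0), (5, 0), (6, 1), (1, 0), (9, 1)])
    def test_threshold_at_five(self, rating, expected):
        assert binarize_rating(rating) == expected

    @pytest.mark.parametrize("rating", [0, 10, -3])
    def test_out_of_range_rejected(self, rating):
        with pytest.raises(ValueError):
            binarize_rating(rating)


class TestMajorityVote:
    def test_examples(self):
        assert majority_vote([1, 1, 0]) == 1
        assert majority_vote([0, 0, 0]) == 0

    def test_all_patterns_match_enumeration(self):
        for votes in itertools.product([0, 1], repeat=3):
            expected = 1 if list(votes).count(1) > list(votes).count(0) else 0
            assert majority_vote(list(votes)) == expected

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([1, 0])


class TestWeightedFusion:
    def test_corner_weight_reproduces_video_exactly(self):
        pv = np.array([0.37, 0.63])
        pair, dec = weighted_fusion(pv, np.array([0.9, 0.1]), np.array([0.2, 0.8]),
                                    FusionWeights(1.0, 0.0, 0.0))
        assert (pair.p_low, pair.p_high) == (0.37, 0.63)
        assert dec == 1

    def test_uniform_weight_arithmetic(self):
        pair, dec = weighted_fusion(
            np.array([0.6, 0.4]), np.array([0.2, 0.8]), np.array([0.4, 0.6]),
            FusionWeights(1 / 3, 1 / 3, 1 / 3))
        assert pair.p_low == pytest.approx(0.4)
        assert pair.p_high == pytest.approx(0.6)
        assert dec == 1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
           st.floats(0.01, 1.0), st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    def test_fused_pair_sums_to_one(self, highs, wa, wb, wc):
        s = wa + wb + wc
        w = FusionWeights(wa / s, wb / s, 1.0 - wa / s - wb / s)
        pairs = [np.array([1 - h, h]) for h in highs]
        fused, _ = weighted_fusion(*pairs, w)
        assert fused.p_low + fused.p_high == pytest.approx(1.0, abs=1e-9)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            FusionWeights(0.5, 0.4, 0.3)


class TestWeightSearch:
    def test_grid_has_5151_triples(self):
        assert fusion_grid_size() == 5151

    def test_perfect_modality_wins(self, rng):
        n = 40
        y = rng.integers(0, 2, size=n)
        perfect = np.column_stack([1.0 - y, y]).astype(float)
        noise1 = rng.random(n)
        noise2 = rng.random(n)
        rand1 = np.column_stack([1 - noise1, noise1])
        rand2 = np.column_stack([1 - noise2, noise2])
        w = search_fusion_weights(rand1, perfect, rand2, y)
        fused = w.a * rand1[:, 1] + w.b * perfect[:, 1] + w.c * rand2[:, 1]
        _, m = confusion_and_metrics((fused >= 0.5).astype(int), y)
        assert m.f1 == 1.0  # F-equivalent ties permitted; result must be perfect

    def test_identical_modalities_tie_resolves_lexicographically(self, rng):
        n = 20
        y = rng.integers(0, 2, size=n)
        p = rng.random(n)
        pair = np.column_stack([1 - p, p])
        w = search_fusion_weights(pair, pair, pair, y)
        assert (w.a, w.b, w.c) == (0.0, 0.0, 1.0)

    def test_missing_modality_rejected(self, rng):
        y = np.array([0, 1, 1])
        p = np.column_stack([1 - np.zeros(3), np.zeros(3)])
        with pytest.raises(ValueError):
            search_fusion_weights(p, p[:2], p, y)

    def test_learned_weights_dominate_corners_on_training_data(self, rng):
        """The searched triple's training F-score >= every single modality."""
        n = 60
        y = rng.integers(0, 2, size=n)
        mods = []
        for k in range(3):
            h = np.clip(y + rng.normal(0, 0.4 + 0.2 * k, size=n), 0, 1)
            mods.append(np.column_stack([1 - h, h]))
        w = search_fusion_weights(*mods, y)

        def train_f1(a, b, c):
            fused = a * mods[0][:, 1] + b * mods[1][:, 1] + c * mods[2][:, 1]
            return confusion_and_metrics((fused >= 0.5).astype(int), y)[1].f1

        best = train_f1(w.a, w.b, w.c)
        for corner in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
            assert best >= train_f1(*corner)


class TestFolds:
    def test_eighteen_subjects_three_per_fold(self):
        plan = make_folds([f"s{i}" for i in range(18)], seed=1)
        assert sorted(len(test) for _, test in plan.folds) == [3] * 6

    def test_twentythree_subjects_fold_sizes(self):
        plan = make_folds([f"s{i}" for i in range(23)], seed=1)
        assert sorted((len(test) for _, test in plan.folds), reverse=True) == \
            [4, 4, 4, 4, 4, 3]

    def test_test_sets_partition_subjects(self):
        subjects = [f"s{i}" for i in range(23)]
        plan = make_folds(subjects, seed=3)
        all_test = [s for _, test in plan.folds for s in test]
        assert sorted(all_test) == sorted(subjects)
        for train, test in plan.folds:
            assert not set(train) & set(test)
            assert sorted(set(train) | set(test)) == sorted(subjects)

    def test_same_seed_same_plan(self):
        subjects = [f"s{i}" for i in range(12)]
        assert make_folds(subjects, seed=9) == make_folds(subjects, seed=9)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], n_folds=6)

    def test_repeated_trial_ids_collapse_to_unique_subjects(self):
        plan = make_folds(["a"] * 5 + ["b"] * 5 + list("cdefgh"), n_folds=4)
        all_test = [s for _, t in plan.folds for s in t]
        assert sorted(all_test) == sorted("abcdefgh")


class TestMetrics:
    def test_worked_arithmetic(self):
        counts, m = confusion_and_metrics(
            [1] * 3 + [1] + [0] * 2 + [0] * 4,
            [1] * 3 + [0] + [1] * 2 + [0] * 4)
        assert counts == ConfusionCounts(tp=3, fp=1, fn=2, tn=4)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.60)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        assert m.accuracy == pytest.approx(0.70)

    def test_perfect_predictions(self):
        _, m = confusion_and_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_degenerate_all_positive_on_all_negative(self):
        _, m = confusion_and_metrics([1, 1, 1], [0, 0, 0])
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([], [])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=50))
    def test_metric_identities(self, pairs):
        pred = [p for p, _ in pairs]
        y = [t for _, t in pairs]
        counts, m = confusion_and_metrics(pred, y)
        assert counts.n == len(pairs)
        assert m.accuracy == pytest.approx((counts.tp + counts.tn) / counts.n)
        if m.precision + m.recall > 0:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall), abs=1e-12)
        else:
            assert m.f1 == 0.0

    def test_fold_average_is_unweighted(self):
        a = MetricSet(accuracy=1.0, precision=1.0, recall=1.0, f1=1.0)
        b = MetricSet(accuracy=0.5, precision=0.0, recall=0.0, f1=0.0)
        avg = average_metrics([a, b])
        assert avg.accuracy == 0.75 and avg.f1 == 0.5
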