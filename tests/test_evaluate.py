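"""Cumulative task scores, severest aggregation, AUC and Cohen's kappa."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octafuse.evaluate import (EyePrediction, UndefinedMetricError,
                               aggregate_severest, auc, cohens_kappa,
                               confusion_matrix, evaluate_model, predict_eye,
                               task_score, task_scores)
from octafuse.synthetic import ValidationError

simplex6 = st.lists(st.floats(0.001, 1.0), min_size=6, max_size=6).map(
    lambda r: np.array(r) / np.sum(r))


class TestTaskScores:
    def test_certain_absence_scores_zero(self):
        assert task_scores([1, 0, 0, 0, 0, 0]).tolist() == [0, 0, 0, 0]

    def test_uniform_distribution_counts_classes(self):
        np.testing.assert_allclose(task_scores(np.full(6, 1 / 6)),
                                   [5 / 6, 4 / 6, 3 / 6, 2 / 6])

    def test_treated_eye_counts_as_proliferative(self):
        assert task_score([0, 0, 0, 0, 0, 1], 3) == 1.0

    def test_out_of_range_task_rejected(self):
        with pytest.raises(ValidationError):
            task_score(np.full(6, 1 / 6), 4)

    @given(simplex6)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scores_non_increasing_in_task(self, p):
        s = task_scores(p)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))


class TestSeverestAggregation:
    def test_single_crop_is_identity(self):
        p = np.array([0.1, 0.5, 0.2, 0.1, 0.05, 0.05])
        prob, scores, grade = aggregate_severest([p])
        np.testing.assert_allclose(prob, p)
        np.testing.assert_allclose(scores, task_scores(p))
        assert grade == 1

    def test_adding_a_crop_never_decreases_scores(self):
        rng = np.random.default_rng(0)
        crops = [rng.dirichlet(np.ones(6)) for _ in range(6)]
        prev = aggregate_severest(crops[:1])[1]
        for k in range(2, 7):
            cur = aggregate_severest(crops[:k])[1]
            assert np.all(cur >= prev - 1e-12)
            prev = cur

    def test_severest_argmax_grade_wins(self):
        p2 = np.array([0, 0, 0.9, 0.1, 0, 0.0])
        p3 = np.array([0, 0, 0.2, 0.6, 0.2, 0.0])
        prob, _, grade = aggregate_severest([p2, p3])
        assert grade == 3
        np.testing.assert_allclose(prob, p3)

    @given(st.lists(simplex6, min_size=2, max_size=6), st.randoms())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_invariance(self, crops, rnd):
        shuffled = list(crops)
        rnd.shuffle(shuffled)
        a = aggregate_severest(crops)
        b = aggregate_severest(shuffled)
        np.testing.assert_allclose(a[1], b[1], atol=1e-12)
        assert a[2] == b[2]

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_severest([])


class ConstantModel:
    def __init__(self, p):
        self.p = np.asarray(p, dtype=np.float64)

    def predict_proba(self, x):
        return np.tile(self.p, (x.shape[0], 1))


class TestPredictEye:
    VOL = np.random.default_rng(1).random((12, 6, 12, 2)).astype(np.float32)

    def test_constant_model_aggregates_to_its_output(self):
        p = np.array([0.1, 0.2, 0.4, 0.1, 0.1, 0.1])
        pred = predict_eye(ConstantModel(p), self.VOL, 7, (6, 6, 6, 2),
                           np.random.default_rng(0))
        np.testing.assert_allclose(pred.prob, p)
        np.testing.assert_allclose(pred.task_scores, task_scores(p))
        assert pred.crop_probs.shape == (7, 6)

    def test_scores_non_decreasing_in_crop_budget(self):
        class CropSensitive:
            def predict_proba(self, x):
                m = x.mean(axis=(1, 2, 3, 4))
                p = np.stack([0.5 - m / 4, 0.5 + m / 4] + [np.zeros_like(m)] * 4, 1)
                return p / p.sum(1, keepdims=True)
        prev = None
        for n in (1, 2, 4, 8):
            pred = predict_eye(CropSensitive(), self.VOL, n, (6, 6, 6, 2),
                               np.random.default_rng(9))   # shared seed prefix
            if prev is not None:
                assert np.all(pred.task_scores >= prev - 1e-12)
            prev = pred.task_scores

    def test_invalid_crop_budget_rejected(self):
        with pytest.raises(ValidationError):
            predict_eye(ConstantModel(np.full(6, 1 / 6)), self.VOL, 0,
                        (6, 6, 6, 2), np.random.default_rng(0))


def _auc_bruteforce(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_chance(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_hand_computed_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_exhaustive_pair_counting_for_all_small_inputs(self):
        rng = np.random.default_rng(0)
        values = [0.0, 0.25, 0.5, 0.5, 1.0]
        for n in range(2, 9):
            for _ in range(60):
                labels = np.zeros(n, int)
                labels[rng.integers(1, n)] = 1
                rng.shuffle(labels)
                if labels.sum() in (0, n):
                    continue
                scores = rng.choice(values, size=n)
                assert abs(auc(scores, labels) -
                           _auc_bruteforce(scores, labels)) < 1e-12

    def test_agrees_with_reference_implementation(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.random(40)
            labels = rng.integers(0, 2, 40)
            if labels.sum() in (0, 40):
                continue
            assert abs(auc(scores, labels) -
                       roc_auc_score(labels, scores)) < 1e-12


def _kappa_recompute(cm):
    """Independent probability-normalised recomputation of the statistic."""
    P = np.asarray(cm, dtype=np.float64)
    P = P / P.sum()
    p0 = sum(P[i, i] for i in range(P.shape[0]))
    pe = sum(P[i, :].sum() * P[:, i].sum() for i in range(P.shape[0]))
    return (p0 - pe) / (1 - pe)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(np.diag([5, 3, 9, 1, 2, 4])) == 1.0

    def test_independent_marginals_give_zero(self):
        row = np.array([10, 5, 25, 8, 2, 4], dtype=float)
        col = np.array([6, 9, 20, 10, 3, 6], dtype=float)
        cm = np.outer(row, col)
        assert abs(cohens_kappa(cm)) < 1e-12

    def test_two_class_hand_computation(self):
        assert abs(cohens_kappa([[40, 10], [20, 30]]) - 0.4) < 1e-12

    def test_thousand_random_matrices_match_recomputation(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            cm = rng.integers(0, 30, (6, 6))
            if cm.sum() == 0:
                continue
            try:
                got = cohens_kappa(cm)
            except UndefinedMetricError:
                continue
            assert abs(got - _kappa_recompute(cm)) < 1e-12

    def test_agrees_with_reference_implementation(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(5)
        for _ in range(20):
            y1 = rng.integers(0, 6, 200)
            y2 = rng.integers(0, 6, 200)
            cm = confusion_matrix(y1, y2)
            assert abs(cohens_kappa(cm) -
                       cohen_kappa_score(y1, y2)) < 1e-10

    def test_degenerate_matrix_undefined(self):
        cm = np.zeros((6, 6))
        cm[2, 2] = 10
        with pytest.raises(UndefinedMetricError):
            cohens_kappa(cm)


def _onehot_prediction(grade):
    p = np.zeros(6)
    p[grade] = 1.0
    return EyePrediction(crop_probs=p[None], prob=p, task_scores=task_scores(p),
                         grade=grade)


class TestEvaluateModel:
    def test_oracle_predictor_is_perfect(self):
        labels = [0, 1, 2, 3, 4, 5, 2, 2, 0, 3]
        preds = [_onehot_prediction(g) for g in labels]
        report = evaluate_model(preds, labels)
        assert report.kappa == 1.0
        np.testing.assert_allclose(report.auc, 1.0)
        assert report.confusion.sum(axis=1).tolist() == \
            np.bincount(labels, minlength=6).tolist()

    def test_label_shuffled_predictor_is_chance(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(6, size=600, p=[.2, .1, .4, .15, .05, .1])
        shuffled = rng.permutation(labels)
        preds = [_onehot_prediction(g) for g in shuffled]
        report = evaluate_model(preds, labels)
        for k in range(4):
            n_pos = (labels >= k + 1).sum()
            n_neg = len(labels) - n_pos
            se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
            assert abs(report.auc[k] - 0.5) <= 4 * se
        assert abs(report.kappa) < 0.1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_model([_onehot_prediction(0)], [0, 1])
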