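"""Confusion metrics, AUC, and clinician-AI fusion."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ccfocus.evaluation import (ClinicianReading, CollabMode, ConfusionCounts,
                                balanced_accuracy, collab_score, confusion,
                                evaluate_predictions, metrics, roc_auc,
                                simulate_collaboration)


def brute_force_report(scores, labels, threshold=0.5):
    """Independent recount straight from the raw lists."""
    tp = sum(1 for s, y in zip(scores, labels) if s >= threshold and y == 1)
    tn = sum(1 for s, y in zip(scores, labels) if s < threshold and y == 0)
    fp = sum(1 for s, y in zip(scores, labels) if s >= threshold and y == 0)
    fn = sum(1 for s, y in zip(scores, labels) if s < threshold and y == 1)
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    rec = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * rec * prec / (rec + prec) if rec + prec else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return acc, prec, rec, f1, spec


def pairwise_auc(scores, labels):
    """Exhaustive pair counting with ties at one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_all_correct(self):
        labels = [1] * 3 + [0] * 7
        scores = [0.9] * 3 + [0.1] * 7
        c = confusion(scores, labels)
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 7, 0, 0)

    def test_all_flipped(self):
        labels = [1] * 3 + [0] * 7
        scores = [0.1] * 3 + [0.9] * 7
        c = confusion(scores, labels)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 7, 3)

    def test_threshold_zero_predicts_everything_positive(self):
        c = confusion([0.0, 0.4, 0.9], [0, 1, 1], threshold=0.0)
        assert c.tn == 0 and c.fn == 0

    def test_string_labels_accepted(self):
        c = confusion([0.9, 0.1], ["agenesis", "normal"])
        assert (c.tp, c.tn) == (1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0.5], [1, 0])


class TestMetrics:
    def test_hand_arithmetic_example(self):
        rep = metrics(ConfusionCounts(tp=9, tn=85, fp=3, fn=3))
        assert rep.accuracy == pytest.approx(0.94)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.75)
        assert rep.f1 == pytest.approx(0.75)

    def test_perfect_counts(self):
        rep = metrics(ConfusionCounts(tp=10, tn=90, fp=0, fn=0))
        for v in (rep.accuracy, rep.precision, rep.recall, rep.f1,
                  rep.balanced_accuracy):
            assert v == 1.0

    def test_balanced_accuracy_identity_holds_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 40, 4)
            if tp + fn == 0 or tn + fp == 0 or tp + tn + fp + fn == 0:
                continue
            rep = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert rep.balanced_accuracy == (rep.sensitivity_agenesis
                                             + rep.specificity_normal) / 2

    def test_reported_balanced_accuracies(self):
        # external test: sens 97.62 / spec 96.55 -> 97.09; internal:
        # 97.50 / 98.08 -> 97.79 (agreement at the printed precision)
        assert balanced_accuracy(0.9762, 0.9655) == pytest.approx(0.9709, abs=5e-5)
        assert balanced_accuracy(0.9750, 0.9808) == pytest.approx(0.9779, abs=5e-5)

    def test_zero_denominator_flagged(self):
        rep = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert rep.recall == 0.0
        assert "recall" in rep.undefined

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_matches_bruteforce_recount_on_random_sets(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            rep = metrics(confusion(scores, labels))
            acc, prec, rec, f1, spec = brute_force_report(scores, labels)
            assert rep.accuracy == pytest.approx(acc, abs=1e-15)
            assert rep.precision == pytest.approx(prec, abs=1e-15)
            assert rep.recall == pytest.approx(rec, abs=1e-15)
            assert rep.f1 == pytest.approx(f1, abs=1e-12)
            assert rep.specificity_normal == pytest.approx(spec, abs=1e-15)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 0, 0]) == 0.5

    def test_single_inversion_matches_pair_counting(self):
        scores = [0.9, 0.3, 0.8, 0.2, 0.1, 0.05]
        labels = [1, 1, 0, 0, 0, 0]
        assert roc_auc(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-15)

    def test_matches_exhaustive_counting_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            scores = rng.integers(0, 5, n) / 4.0  # force ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestCollabScore:
    def test_junior_mode_arithmetic(self):
        fused, decision = collab_score(
            0.9, ClinicianReading("agenesis", 0.5), CollabMode("junior"))
        assert fused == pytest.approx(0.78)
        assert decision == "agenesis"

    def test_senior_boundary_inclusive(self):
        fused, decision = collab_score(
            0.6, ClinicianReading("agenesis", 0.4), CollabMode("senior"))
        assert fused == pytest.approx(0.5)
        assert decision == "agenesis"

    def test_convexity_fixed_point(self):
        for mode in ("junior", "senior"):
            fused, _ = collab_score(0.37, ClinicianReading("agenesis", 0.37),
                                    CollabMode(mode))
            assert fused == pytest.approx(0.37)

    def test_normal_diagnosis_flips_confidence(self):
        fused, _ = collab_score(0.0, ClinicianReading("normal", 0.9),
                                CollabMode("senior"))
        assert fused == pytest.approx(0.05)  # p_c = 1 - 0.9

    def test_monotone_in_both_inputs(self):
        mode = CollabMode("junior")
        r = ClinicianReading("agenesis", 0.6)
        f1, _ = collab_score(0.2, r, mode)
        f2, _ = collab_score(0.8, r, mode)
        assert f2 > f1
        f3, _ = collab_score(0.5, ClinicianReading("agenesis", 0.2), mode)
        f4, _ = collab_score(0.5, ClinicianReading("agenesis", 0.9), mode)
        assert f4 > f3

    def test_senior_mode_moves_toward_clinician(self):
        ai, reading = 0.9, ClinicianReading("agenesis", 0.3)
        junior, _ = collab_score(ai, reading, CollabMode("junior"))
        senior, _ = collab_score(ai, reading, CollabMode("senior"))
        assert abs(senior - reading.prob_agenesis) < abs(junior - reading.prob_agenesis)

    def test_weights_complementary(self):
        for mode in ("junior", "senior"):
            m = CollabMode(mode)
            assert m.ai_weight + m.clinician_weight == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            collab_score(1.2, ClinicianReading("normal", 0.5),
                         CollabMode("junior"))
        with pytest.raises(ValueError):
            ClinicianReading("agenesis", 1.5)
        with pytest.raises(ValueError):
            CollabMode("resident")


class TestSimulateCollaboration:
    def test_perfect_confident_clinician_dominates_senior_mode(self):
        out = simulate_collaboration(2000, ai_accuracy=0.8,
                                     clinician_accuracy=1.0,
                                     mode=CollabMode("senior"), seed=0,
                                     conf_correct=(1.0, 1.0))
        assert out["accuracy_fused"] == 1.0

    def test_fused_not_below_partners_at_matched_accuracy(self):
        out = simulate_collaboration(10_000, 0.9, 0.9, CollabMode("senior"),
                                     seed=1)
        sd3 = 3 * np.sqrt(0.9 * 0.1 / 10_000)
        assert out["accuracy_fused"] >= out["accuracy_ai"] - sd3
        assert out["accuracy_fused"] >= out["accuracy_clinician"] - sd3

    def test_output_weights_sum_to_one(self):
        out = simulate_collaboration(100, 0.9, 0.9, CollabMode("junior"), seed=2)
        assert out["ai_weight"] + out["clinician_weight"] == 1.0

    def test_invalid_accuracy_rejected(self):
        with pytest.raises(ValueError):
            simulate_collaboration(10, 0.4, 0.9, CollabMode("junior"))
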