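import numpy as np
import pytest

from pwvnet.evaluate import (ConfusionMatrix, class_metrics, confusion,
                             repeated_holdout, shockable_metrics, train)
from pwvnet.models import build_model, cnn2_spec
from pwvnet.preprocess import RhythmClass

N, O, VT, VF = (RhythmClass.NORMAL, RhythmClass.OTHER,
                RhythmClass.VT, RhythmClass.VF)


def balanced_labels(n_per_class=100):
    return np.repeat([int(c) for c in (N, O, VT, VF)], n_per_class)


class TestRepeatedHoldout:
    def test_67_33_split_per_class(self):
        labels = balanced_labels(100)
        for tr, te in repeated_holdout(labels, seed=0):
            for c in range(4):
                assert np.sum(labels[tr] == c) == 67
                assert np.sum(labels[te] == c) == 33

    def test_partitions_disjoint_and_exhaustive(self):
        labels = balanced_labels(17)
        for tr, te in repeated_holdout(labels, seed=1):
            assert len(np.intersect1d(tr, te)) == 0
            assert len(np.union1d(tr, te)) == len(labels)

    def test_deterministic_in_seed(self):
        labels = balanced_labels(20)
        a = repeated_holdout(labels, seed=9)
        b = repeated_holdout(labels, seed=9)
        for (t1, e1), (t2, e2) in zip(a, b):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(e1, e2)

    def test_repeats_differ(self):
        labels = balanced_labels(50)
        splits = repeated_holdout(labels, seed=3)
        assert any(not np.array_equal(splits[0][0], s[0]) for s in splits[1:])

    def test_missing_class_rejected(self):
        labels = np.repeat([0, 1, 2], 30)  # no VF at all
        with pytest.raises(ValueError):
            repeated_holdout(labels)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = balanced_labels(5)
        cm = confusion(y, y)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert cm.total == len(y)

    def test_hand_enumerated_example(self):
        truths = [int(VF), int(VF), int(VT)]
        preds = [int(VF), int(VT), int(VT)]
        cm = confusion(truths, preds)
        assert cm.counts[int(VF), int(VF)] == 1
        assert cm.counts[int(VF), int(VT)] == 1
        assert cm.counts[int(VT), int(VT)] == 1
        assert cm.total == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-np.ones((4, 4)))


def cm_with_one_vs_rest(target, tp, fn, fp, tn):
    """Build a 4x4 matrix realizing the given one-vs-rest counts."""
    counts = np.zeros((4, 4), dtype=int)
    others = [c for c in range(4) if c != int(target)]
    counts[int(target), int(target)] = tp
    counts[int(target), others[0]] = fn
    counts[others[1], int(target)] = fp
    counts[others[1], others[1]] = tn
    return ConfusionMatrix(counts)


class TestClassMetrics:
    def test_perfect_binary_case(self):
        cm = cm_with_one_vs_rest(VF, 50, 0, 0, 50)
        m = class_metrics(cm, VF)
        assert (m["sensitivity"], m["spe_global"], m["accuracy"], m["f_score"]) \
            == (100.0, 100.0, 100.0, 100.0)

    def test_hand_worked_formula_example(self):
        """TP=8 FN=2 FP=1 TN=89 -> sens 80.00, spe 98.89, acc 97.00, F 84.21."""
        m = class_metrics(cm_with_one_vs_rest(VF, 8, 2, 1, 89), VF)
        assert m["sensitivity"] == pytest.approx(80.00, abs=0.005)
        assert m["spe_global"] == pytest.approx(98.89, abs=0.005)
        assert m["accuracy"] == pytest.approx(97.00, abs=0.005)
        assert m["f_score"] == pytest.approx(84.21, abs=0.005)

    def test_f_score_equals_harmonic_mean_form(self, rng):
        for _ in range(20):
            cm = ConfusionMatrix(rng.integers(1, 40, size=(4, 4)))
            for target in (N, O, VT, VF):
                m = class_metrics(cm, target)
                c = cm.counts
                tp = c[int(target), int(target)]
                fp = c[:, int(target)].sum() - tp
                fn = c[int(target)].sum() - tp
                precision = tp / (tp + fp)
                recall = tp / (tp + fn)
                harmonic = 200 * precision * recall / (precision + recall)
                assert m["f_score"] == pytest.approx(harmonic)

    def test_per_class_specificity_columns(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[int(N), int(VF)] = 2   # 2 of 10 Normal called VF
        counts[int(N), int(N)] = 8
        counts[int(VF), int(VF)] = 5
        m = class_metrics(ConfusionMatrix(counts), VF)
        assert m["spe_vs"]["NORMAL"] == pytest.approx(80.0)

    def test_absent_class_metric_is_undefined_not_zero(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[int(N), int(N)] = 10
        m = class_metrics(ConfusionMatrix(counts), VF)
        assert m["sensitivity"] is None

    def test_invariant_to_permuting_other_classes(self, rng):
        cm = ConfusionMatrix(rng.integers(0, 30, size=(4, 4)))
        m1 = class_metrics(cm, N)
        perm = [int(N), int(VT), int(O), int(VF)]  # swap Other <-> VT
        m2 = class_metrics(ConfusionMatrix(cm.counts[np.ix_(perm, perm)]), N)
        for key in ("sensitivity", "spe_global", "accuracy", "f_score"):
            assert m1[key] == pytest.approx(m2[key])

    def test_trace_consistency_across_classes(self, rng):
        cm = ConfusionMatrix(rng.integers(0, 30, size=(4, 4)))
        tp_sum = sum(cm.counts[int(c), int(c)] for c in (N, O, VT, VF))
        assert tp_sum == np.trace(cm.counts)

    def test_majority_classifier_gives_zero_minority_sensitivity(self):
        y = balanced_labels(10)
        pred = np.full_like(y, int(N))
        cm = confusion(y, pred)
        for c in (O, VT, VF):
            assert class_metrics(cm, c)["sensitivity"] == 0.0


class TestShockableMetrics:
    def test_diagonal_is_perfect(self):
        cm = confusion(balanced_labels(5), balanced_labels(5))
        m = shockable_metrics(cm)
        assert (m["sensitivity"], m["specificity"], m["accuracy"]) \
            == (100.0, 100.0, 100.0)

    def test_vt_vf_confusion_is_not_an_error(self):
        y = balanced_labels(5)
        pred = y.copy()
        pred[y == int(VT)] = int(VF)  # every VT called VF
        m = shockable_metrics(confusion(y, pred))
        assert (m["sensitivity"], m["specificity"], m["accuracy"]) \
            == (100.0, 100.0, 100.0)

    def test_single_vf_miss_arithmetic(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[int(VF), int(VF)] = 9
        counts[int(VF), int(N)] = 1     # one VF called Normal
        counts[int(N), int(N)] = 45
        counts[int(O), int(O)] = 45     # 90 correct negatives
        m = shockable_metrics(ConfusionMatrix(counts))
        assert m["sensitivity"] == pytest.approx(90.00)
        assert m["specificity"] == pytest.approx(100.00)
        assert m["accuracy"] == pytest.approx(99.00)


class TestTrain:
    def test_zero_epochs_leaves_model_at_initialization(self, rng):
        model = build_model(cnn2_spec(), seed=0)
        before = model.net.get_weights()
        train(model, rng.random((8, 180, 180)), np.arange(8) % 4, epochs=0)
        for a, b in zip(before, model.net.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_empty_training_set_rejected(self):
        model = build_model(cnn2_spec(), seed=0)
        with pytest.raises(ValueError):
            train(model, np.empty((0, 180, 180)), np.empty(0), epochs=1)

    def test_seeded_training_is_reproducible(self, rng):
        x = rng.random((12, 180, 180)).astype(np.float32)
        y = np.arange(12) % 4
        finals = []
        for _ in range(2):
            model = build_model(cnn2_spec(), seed=4)
            hist = train(model, x, y, epochs=2, seed=11)
            finals.append(hist["loss"][-1])
        assert finals[0] == finals[1]

    def test_separable_images_reach_high_train_accuracy(self, rng):
        """CNN2 fits a small linearly separable image set to >=99%."""
        n_per = 30
        x = np.zeros((4 * n_per, 180, 180), dtype=np.float32)
        y = np.repeat(np.arange(4), n_per)
        for i, c in enumerate(y):  # distinct bright quadrant per class
            r, col = divmod(int(c), 2)
            x[i, r * 90:(r + 1) * 90, col * 90:(col + 1) * 90] = 1.0
        x += 0.05 * rng.random(x.shape).astype(np.float32)
        model = build_model(cnn2_spec(), seed=2)
        hist = train(model, x, y, epochs=15, seed=3)
        assert hist["accuracy"][-1] >= 0.99
        assert len(hist["loss"]) == 15

    def test_validation_history_tracked(self, rng):
        x = rng.random((8, 180, 180)).astype(np.float32)
        y = np.arange(8) % 4
        model = build_model(cnn2_spec(), seed=0)
        hist = train(model, x, y, epochs=2, validation=(x, y))
        assert len(hist["val_loss"]) == 2 and len(hist["val_accuracy"]) == 2
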