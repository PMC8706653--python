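"""Confusion matrix, macro metrics, F1 and k-fold protocol.

The brute-force oracle tallies TP/FP/FN/TN per class by explicit
enumeration, independent of the vectorized implementation; sklearn serves
as a second, external cross-check where its definitions coincide.
"""

import numpy as np
import pytest

from harfusion import (
    CVConfig,
    ModelConfig,
    TrainConfig,
    ZoneSpec,
    accuracy,
    confusion,
    f1_from_macros,
    kfold_cv,
    macro_precision_recall,
)
from harfusion.evaluation import (
    ConfusionMatrix,
    kfold_indices,
    macro_f1_per_class,
    metrics_report,
    one_vs_rest_accuracy,
)


def brute_force_metrics(y_true, y_pred, n=6):
    """Explicit one-vs-rest tally in exact integer arithmetic."""
    counts = [[0] * n for _ in range(n)]
    for t, p in zip(y_true, y_pred):
        counts[t][p] += 1
    total = len(y_true)
    per_class = []
    for i in range(n):
        tp = counts[i][i]
        fp = sum(counts[r][i] for r in range(n)) - tp
        fn = sum(counts[i][c] for c in range(n)) - tp
        tn = total - tp - fp - fn
        per_class.append((tp, fp, fn, tn))
    acc = 100.0 * sum(counts[i][i] for i in range(n)) / total
    prec = [100.0 * tp / (tp + fp) if tp + fp else 0.0 for tp, fp, _, _ in per_class]
    rec = [100.0 * tp / (tp + fn) if tp + fn else 0.0 for tp, _, fn, _ in per_class]
    return counts, per_class, acc, prec, rec


class TestConfusion:
    def test_identity_diagonal(self):
        y = np.arange(6)
        cm = confusion(y, y)
        np.testing.assert_array_equal(cm.counts, np.eye(6, dtype=int))

    def test_hand_count(self):
        cm = confusion([0, 0, 1], [0, 1, 1])
        assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1 and cm.counts[1, 1] == 1
        assert cm.total == 3

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])

    def test_tp_fp_fn_tn_sum_to_total(self, rng):
        y_true = rng.integers(0, 6, 200)
        y_pred = rng.integers(0, 6, 200)
        cm = confusion(y_true, y_pred)
        for i in range(6):
            assert cm.tp(i) + cm.fp(i) + cm.fn(i) + cm.tn(i) == cm.total


class TestMetricsAgainstBruteForce:
    def test_500_random_pairs_exact(self, rng):
        """Accuracy and per-class precision/recall match the explicit
        tally exactly on >= 500 random label/prediction vectors."""
        for _ in range(500):
            m = int(rng.integers(2, 40))
            y_true = rng.integers(0, 6, m)
            y_pred = rng.integers(0, 6, m)
            cm = confusion(y_true, y_pred)
            counts, per_class, acc, prec, rec = brute_force_metrics(
                y_true.tolist(), y_pred.tolist()
            )
            np.testing.assert_array_equal(cm.counts, counts)
            assert accuracy(cm) == acc
            with pytest.warns(UserWarning) if any(
                tp + fp == 0 or tp + fn == 0 for tp, fp, fn, _ in per_class
            ) else _nullcontext():
                p_macro, r_macro, p_i, r_i, _ = macro_precision_recall(cm)
            assert p_i == prec and r_i == rec
            assert p_macro == pytest.approx(np.mean(prec), abs=0)
            assert r_macro == pytest.approx(np.mean(rec), abs=0)

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import confusion_matrix, precision_score, recall_score

        y_true = rng.integers(0, 6, 300)
        y_pred = rng.integers(0, 6, 300)
        cm = confusion(y_true, y_pred)
        np.testing.assert_array_equal(
            cm.counts, confusion_matrix(y_true, y_pred, labels=range(6))
        )
        p_macro, r_macro, *_ = macro_precision_recall(cm)
        assert p_macro == pytest.approx(
            100 * precision_score(y_true, y_pred, average="macro", zero_division=0)
        )
        assert r_macro == pytest.approx(
            100 * recall_score(y_true, y_pred, average="macro", zero_division=0)
        )


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


class TestAccuracy:
    def test_perfect_diagonal_is_100(self):
        cm = ConfusionMatrix(np.diag([3, 4, 5, 6, 7, 8]))
        assert accuracy(cm) == 100.0

    def test_hand_computed_3class(self):
        counts = np.array([[8, 1, 1], [2, 7, 1], [0, 0, 5]])
        assert accuracy(ConfusionMatrix(counts)) == pytest.approx(80.0)

    def test_permutation_invariant(self, rng):
        counts = rng.integers(0, 20, (6, 6))
        perm = rng.permutation(6)
        a1 = accuracy(ConfusionMatrix(counts))
        a2 = accuracy(ConfusionMatrix(counts[np.ix_(perm, perm)]))
        assert a1 == pytest.approx(a2)

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(np.zeros((6, 6), dtype=int)))

    def test_one_vs_rest_variant_distinct(self):
        counts = np.array([[8, 1, 1], [2, 7, 1], [0, 0, 5]])
        cm = ConfusionMatrix(counts)
        # per class: (TP+TN)/total = 21/25, 21/25, 23/25
        assert one_vs_rest_accuracy(cm) == pytest.approx(100 * (21 + 21 + 23) / 75)
        # binary-averaged reading is higher than multiclass accuracy here
        assert one_vs_rest_accuracy(cm) > accuracy(cm)


class TestMacro:
    def test_perfect_all_100(self):
        cm = ConfusionMatrix(np.eye(6, dtype=int) * 5)
        p_macro, r_macro, p_i, r_i, deg = macro_precision_recall(cm)
        assert p_macro == r_macro == 100.0
        assert deg == []

    def test_never_predicted_class_flagged_zero(self):
        y_true = [0, 1, 2, 3, 4, 5]
        y_pred = [0, 1, 2, 3, 4, 4]  # class 5 never predicted
        cm = confusion(y_true, y_pred)
        with pytest.warns(UserWarning, match="degenerate"):
            p_macro, _, p_i, _, deg = macro_precision_recall(cm)
        assert 5 in deg and p_i[5] == 0.0
        assert p_macro == pytest.approx(np.mean(p_i))


class TestF1:
    @pytest.mark.parametrize(
        "p,r,expected",
        [(80.0, 80.0, 80.0), (100.0, 0.0, 0.0), (60.0, 40.0, 48.0), (0.0, 0.0, 0.0)],
    )
    def test_closed_forms(self, p, r, expected):
        assert f1_from_macros(p, r) == pytest.approx(expected)

    def test_per_class_macro_f1_differs_in_general(self, rng):
        y_true = rng.integers(0, 6, 100)
        y_pred = rng.integers(0, 6, 100)
        cm = confusion(y_true, y_pred)
        rep = metrics_report(cm)
        # both F1 variants are defined and bounded
        assert 0 <= rep.f1 <= 100 and 0 <= rep.f1_per_class_macro <= 100
        assert macro_f1_per_class(cm) == rep.f1_per_class_macro


class TestKFold:
    def test_20_items_k10_fold_sizes(self):
        labels = np.tile(np.arange(2), 10)
        folds = kfold_indices(labels, CVConfig(k=10, seed=0))
        assert all(len(f) == 2 for f in folds)
        union = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(union, np.arange(20))

    def test_10299_items_k10_sizes(self):
        labels = np.zeros(10299, dtype=int)
        folds = kfold_indices(labels, CVConfig(k=10, seed=1, stratified=False))
        sizes = sorted(len(f) for f in folds)
        assert sizes == [1029] + [1030] * 9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("stratified", [True, False])
    def test_partition_property(self, seed, stratified, rng):
        labels = rng.integers(0, 6, 173)
        folds = kfold_indices(labels, CVConfig(k=7, seed=seed, stratified=stratified))
        union = np.concatenate(folds)
        assert len(union) == len(set(union.tolist())) == 173
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1 or stratified
        # reproducible under the same seed
        folds2 = kfold_indices(labels, CVConfig(k=7, seed=seed, stratified=stratified))
        for a, b in zip(folds, folds2):
            np.testing.assert_array_equal(a, b)

    def test_k_larger_than_size_fatal(self):
        with pytest.raises(ValueError):
            kfold_indices(np.zeros(5, int), CVConfig(k=10))

    def test_stratified_fold_class_balance(self, rng):
        labels = np.repeat(np.arange(6), 30)
        folds = kfold_indices(labels, CVConfig(k=10, seed=3))
        for f in folds:
            counts = np.bincount(labels[f], minlength=6)
            assert counts.max() - counts.min() <= 1

    def test_cv_smoke_on_simulated_set(self, sim_small):
        """3-fold CV with a shrunken model: partition respected, reports
        produced, fresh model per fold."""
        from harfusion.preprocess import fit_minmax, normalize

        ws = normalize(sim_small, fit_minmax(sim_small))
        cfg = ModelConfig(
            window_len=ws.window_len,
            zones=(ZoneSpec(1, (2, 3, 4)), ZoneSpec(3, (2, 3, 4))),
            fc_widths=(8, 12),
            seed=0,
        )
        tc = TrainConfig(max_epochs=2, batch_size=32, seed=0)
        reports, pooled, mean_acc = kfold_cv(ws, cfg, tc, CVConfig(k=3, seed=0))
        assert len(reports) == 3
        assert 0 <= mean_acc <= 100
        # equal fold sizes (120/3): pooled accuracy equals the fold mean
        assert pooled.accuracy == pytest.approx(mean_acc)
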