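"""Metrics, k-fold CV, ROC/AUC, and the multiclass confusion matrix."""

import itertools
import math
import warnings

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from bachbpred.errors import ValidationError
from bachbpred.evaluation import (
    ConfusionCounts,
    compute_metrics,
    confusion_from_predictions,
    cross_validate,
    kfold_split,
    multiclass_confusion,
    roc_auc,
)
from bachbpred.svm import SVMParams, decision_scores, train


def metrics_oracle(tp, tn, fp, fn):
    """Direct substitution into the defining formulas."""
    total = tp + tn + fp + fn
    acc = 100.0 * (tp + tn) / total
    sn = 100.0 * tp / (tp + fn) if tp + fn else None
    sp = 100.0 * tn / (tn + fp) if tn + fp else None
    fpr = 100.0 * fp / (fp + tn) if fp + tn else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None
    return acc, sn, sp, fpr, mcc


class TestComputeMetrics:
    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert (rep.acc, rep.sn, rep.sp, rep.mcc, rep.fpr) == (100, 100, 100, 1, 0)

    def test_chance_symmetry(self):
        rep = compute_metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert rep.acc == 50 and rep.mcc == 0

    def test_derived_example(self):
        rep = compute_metrics(ConfusionCounts(tp=90, tn=80, fp=20, fn=10))
        assert rep.sn == pytest.approx(90)
        assert rep.sp == pytest.approx(80)
        assert rep.acc == pytest.approx(85)
        assert rep.mcc == pytest.approx((90 * 80 - 20 * 10) / math.sqrt(110 * 100 * 100 * 90))

    def test_matches_oracle_over_exhaustive_grid(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for tp, tn, fp, fn in itertools.product(range(7), repeat=4):
                if tp + tn + fp + fn == 0:
                    continue
                rep = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
                acc, sn, sp, fpr, mcc = metrics_oracle(tp, tn, fp, fn)
                assert rep.acc == pytest.approx(acc)
                assert rep.sn == (pytest.approx(sn) if sn is not None else None)
                assert rep.sp == (pytest.approx(sp) if sp is not None else None)
                assert rep.fpr == (pytest.approx(fpr) if fpr is not None else None)
                if mcc is None:
                    assert rep.mcc is None
                else:
                    assert rep.mcc == pytest.approx(mcc)
                    assert -1 <= rep.mcc <= 1

    def test_mcc_symmetric_under_class_swap(self):
        for tp, tn, fp, fn in [(5, 3, 2, 1), (9, 0, 4, 7), (1, 1, 6, 2)]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a = compute_metrics(ConfusionCounts(tp, tn, fp, fn)).mcc
                b = compute_metrics(ConfusionCounts(tn, tp, fn, fp)).mcc
            assert a == pytest.approx(b)

    def test_zero_marginal_is_undefined_with_warning(self):
        with pytest.warns(UserWarning) as caught:
            rep = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=2, fn=0))
        messages = [str(w.message) for w in caught]
        assert any("SN undefined" in m for m in messages)
        assert any("MCC undefined" in m for m in messages)
        assert rep.sn is None and rep.mcc is None

    def test_fpr_complements_sp(self):
        rep = compute_metrics(ConfusionCounts(tp=10, tn=30, fp=10, fn=5))
        assert rep.fpr == pytest.approx(100 - rep.sp)


class TestKFoldSplit:
    def test_exact_division(self):
        ids = [f"i{k}" for k in range(10)]
        assignment = kfold_split(ids, k=5, seed=0)
        sizes = sorted(len(assignment.ids_in_fold(f)) for f in range(5))
        assert sizes == [2, 2, 2, 2, 2]

    def test_near_equal_sizes(self):
        ids = [f"i{k}" for k in range(11)]
        sizes = sorted(
            len(kfold_split(ids, k=5, seed=1).ids_in_fold(f)) for f in range(5)
        )
        assert sizes == [2, 2, 2, 2, 3]

    def test_deterministic_under_seed(self):
        ids = [f"i{k}" for k in range(23)]
        assert kfold_split(ids, 5, seed=7).folds == kfold_split(ids, 5, seed=7).folds
        assert kfold_split(ids, 5, seed=7).folds != kfold_split(ids, 5, seed=8).folds

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValidationError):
            kfold_split(["a", "b"], k=3, seed=0)

    def test_stratified_sizes_still_balanced(self):
        ids = [f"i{k}" for k in range(21)]
        labels = {i: ("pos" if k < 6 else "neg") for k, i in enumerate(ids)}
        assignment = kfold_split(ids, k=5, seed=3, stratify_by=labels)
        sizes = [len(assignment.ids_in_fold(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1
        # every fold sees at least one member of the minority class
        for f in range(5):
            assert any(labels[i] == "pos" for i in assignment.ids_in_fold(f))


class TestCrossValidate:
    def test_separable_classes_are_perfect(self, rng):
        X = np.vstack([rng.normal(-3, 0.2, (30, 2)), rng.normal(3, 0.2, (30, 2))])
        y = np.array([-1] * 30 + [1] * 30)
        summary = cross_validate(X, y, SVMParams(gamma=1.0, cost=100.0), k=5, seed=0)
        assert summary.pooled.acc == 100.0
        assert summary.sd_acc == 0.0

    def test_permuted_labels_near_chance(self, rng):
        X = rng.normal(size=(200, 5))
        y = np.array([1, -1] * 100)
        summary = cross_validate(X, y, SVMParams(gamma=0.5, cost=10.0), k=5, seed=1)
        assert abs(summary.pooled.acc - 50.0) <= 12.0  # binomial noise at n=200

    def test_leave_one_out_matches_brute_force(self, rng):
        X = np.vstack([rng.normal(-2, 0.5, (3, 2)), rng.normal(2, 0.5, (3, 2))])
        y = np.array([-1, -1, -1, 1, 1, 1])
        ids = [str(i) for i in range(6)]
        params = SVMParams(gamma=1.0, cost=10.0)
        summary = cross_validate(
            X, y, params, ids=ids, k=6, seed=0, stratify=False
        )
        # brute-force LOO: same folds, trained and scored by hand
        assignment = kfold_split(ids, k=6, seed=0)
        correct = 0
        for i, rec_id in enumerate(ids):
            fold = assignment.folds[rec_id]
            mask = np.array([assignment.folds[j] != fold for j in ids])
            model = train(X[mask], y[mask], params, seed=0, scheme="t2")
            pred = 1 if decision_scores(model, X[i : i + 1])[0] >= 0 else -1
            correct += pred == y[i]
        assert summary.pooled.acc == pytest.approx(100.0 * correct / 6)

    def test_pooled_counts_cover_dataset(self, rng):
        X = rng.normal(size=(37, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        if len(set(y.tolist())) < 2:
            pytest.skip("degenerate draw")
        summary = cross_validate(X, y, SVMParams(gamma=1.0, cost=5.0), k=5, seed=2)
        assert summary.pooled.counts.total == 37

    def test_mean_sd_recomputable_from_folds(self, rng):
        X = np.vstack([rng.normal(-1, 1, (25, 2)), rng.normal(1, 1, (25, 2))])
        y = np.array([-1] * 25 + [1] * 25)
        summary = cross_validate(X, y, SVMParams(gamma=1.0, cost=5.0), k=5, seed=3)
        accs = summary.fold_accuracies
        assert summary.mean_acc == pytest.approx(np.mean(accs))
        assert summary.sd_acc == pytest.approx(np.std(accs, ddof=1))


class TestRocAuc:
    def test_perfect_separation(self):
        curve, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1])
        assert auc == 1.0
        assert (1.0, 1.0) in curve

    def test_anti_perfect(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, -1, -1])
        assert auc == 0.0

    def test_all_ties_give_half(self):
        _, auc = roc_auc([0.5] * 6, [1, 1, 1, -1, -1, -1])
        assert auc == pytest.approx(0.5)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_mann_whitney(self, rng):
        for _ in range(30):
            n_pos, n_neg = rng.integers(3, 30), rng.integers(3, 30)
            scores = np.concatenate(
                [rng.normal(0.5, 1, n_pos), rng.normal(0, 1, n_neg)]
            ).round(1)  # rounding forces ties
            labels = np.array([1] * n_pos + [-1] * n_neg)
            _, auc = roc_auc(scores, labels)
            u_stat = mannwhitneyu(scores[labels == 1], scores[labels == -1]).statistic
            assert auc == pytest.approx(u_stat / (n_pos * n_neg))

    def test_complement_symmetry_without_ties(self, rng):
        scores = rng.permutation(np.linspace(0, 1, 20))
        labels = np.array([1] * 10 + [-1] * 10)
        _, auc_fwd = roc_auc(scores, labels)
        _, auc_rev = roc_auc(-scores, labels)
        assert auc_fwd + auc_rev == pytest.approx(1.0)


class TestMulticlassConfusion:
    def test_all_correct_is_diagonal(self):
        truth = {"a": "sHb", "b": "flavoHb", "c": "trHb"}
        matrix = multiclass_confusion(truth, truth)
        assert (np.diag(matrix.values) == 1).all()
        assert matrix.values.sum() == 3

    def test_symmetric_swap_off_diagonal(self):
        truth = {"a": "flavoHb", "b": "trHb", "c": "sHb"}
        pred = {"a": "trHb", "b": "flavoHb", "c": "sHb"}
        matrix = multiclass_confusion(pred, truth)
        assert matrix.loc["flavoHb", "trHb"] == 1
        assert matrix.loc["trHb", "flavoHb"] == 1
        assert matrix.loc["sHb", "sHb"] == 1

    def test_row_sums_equal_class_totals(self):
        truth = {"a": "x", "b": "x", "c": "y"}
        pred = {"a": "x", "b": "y", "c": "y"}
        matrix = multiclass_confusion(pred, truth)
        assert matrix.loc["x"].sum() == 2 and matrix.loc["y"].sum() == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            multiclass_confusion({}, {})

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            multiclass_confusion({"a": "x"}, {"b": "x"})


def test_confusion_from_predictions_counts():
    counts = confusion_from_predictions([1, 1, -1, -1], [1, -1, -1, 1])
    assert (counts.tp, counts.fn, counts.tn, counts.fp) == (1, 1, 1, 1)
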