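"""Focal loss closed forms and the evaluation-report oracle equivalence."""

import math

import numpy as np
import pytest

from ddikg.loss_metrics import (class_weights, evaluate, multi_focal_loss,
                                pr_points, roc_points)


class TestClassWeights:
    def test_corpus_scale_counts_ratio(self):
        # five-class counts of a processed DDI training set
        counts = [16160, 697, 1347, 157, 1193]
        w = class_weights(counts)
        assert w.alpha[0] == pytest.approx(16160 / 19554, abs=1e-12)
        assert w.alpha[0] == pytest.approx(0.8264, abs=5e-5)

    def test_equal_counts_give_uniform_weights(self):
        w = class_weights([7, 7, 7, 7, 7])
        assert np.allclose(w.alpha, 0.2, atol=1e-15)

    @pytest.mark.parametrize("counts", [[1, 2, 3], [100, 1], [5, 0, 5]])
    def test_weights_always_normalised(self, counts):
        assert class_weights(counts).alpha.sum() == pytest.approx(1.0)
        assert class_weights(counts, "inverse").alpha.sum() == \
            pytest.approx(1.0)

    def test_inverse_weighting_upweights_rare_classes(self):
        w = class_weights([100, 10, 1], weighting="inverse")
        assert w.alpha[2] > w.alpha[1] > w.alpha[0]

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            class_weights([0, 0, 0])


class TestMultiFocalLoss:
    def test_perfect_prediction_gives_zero_loss(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        assert multi_focal_loss(probs, [0], [1.0, 0.0, 0.0]) == 0.0

    def test_hand_value_quarter_log_two(self):
        probs = np.array([[0.5, 0.5]])
        loss = multi_focal_loss(probs, [0], alpha=[1.0, 0.0], gamma=2.0)
        assert loss == pytest.approx(0.25 * math.log(2.0), abs=1e-10)

    def test_gamma_zero_reduces_to_weighted_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(20, 5))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        labels = rng.integers(0, 5, size=20)
        alpha = np.full(5, 0.2)
        loss = multi_focal_loss(probs, labels, alpha, gamma=0.0)
        ce = np.mean([-alpha[y] * math.log(probs[i, y])
                      for i, y in enumerate(labels)])
        assert loss == pytest.approx(ce, abs=1e-12)

    def test_printed_sum_form_is_constant_rescaling(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(5), size=10)
        labels = rng.integers(0, 5, size=10)
        alpha = np.array([0.5, 0.2, 0.1, 0.1, 0.1])
        printed = multi_focal_loss(probs, labels, alpha,
                                   focal_form="printed_sum")
        unweighted = multi_focal_loss(probs, labels, np.ones(5), gamma=2.0)
        assert printed == pytest.approx(unweighted * alpha.sum() / 5,
                                        abs=1e-12)

    def test_monotone_decreasing_in_true_probability(self):
        losses = [multi_focal_loss(np.array([[p, 1 - p]]), [0], [1.0, 0.0])
                  for p in (0.1, 0.3, 0.5, 0.7, 0.9, 0.999)]
        assert losses == sorted(losses, reverse=True)

    def test_focal_downweights_relative_to_cross_entropy(self):
        probs = np.array([[0.7, 0.3]])
        f2 = multi_focal_loss(probs, [0], [1.0, 0.0], gamma=2.0)
        f0 = multi_focal_loss(probs, [0], [1.0, 0.0], gamma=0.0)
        assert 0 < f2 < f0

    def test_zero_probability_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            loss = multi_focal_loss(np.array([[0.0, 1.0]]), [0], [1.0, 0.0])
        assert np.isfinite(loss)


# ---------------------------------------------------------------------------
# independent brute-force oracles (pure python, no shared code path)
# ---------------------------------------------------------------------------

def oracle_prf(gold, pred, scope_classes, m):
    per = {}
    for c in range(m):
        tp = sum(1 for g, p in zip(gold, pred) if g == c and p == c)
        fp = sum(1 for g, p in zip(gold, pred) if g != c and p == c)
        fn = sum(1 for g, p in zip(gold, pred) if g == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        per[c] = (tp, fp, fn, prec, rec)
    tps = sum(per[c][0] for c in scope_classes)
    fps = sum(per[c][1] for c in scope_classes)
    fns = sum(per[c][2] for c in scope_classes)
    micro_p = tps / (tps + fps) if tps + fps else 0.0
    micro_r = tps / (tps + fns) if tps + fns else 0.0
    macro_p = sum(per[c][3] for c in scope_classes) / len(scope_classes)
    macro_r = sum(per[c][4] for c in scope_classes) / len(scope_classes)

    def h(p, r):
        return 2 * p * r / (p + r) if p + r else 0.0

    return per, micro_p, micro_r, h(micro_p, micro_r), macro_p, macro_r, \
        h(macro_p, macro_r)


def oracle_roc_auc(y, s):
    thresholds = sorted(set(s), reverse=True)
    pos = sum(y)
    neg = len(y) - pos
    pts = [(0.0, 0.0)]
    for thr in thresholds:
        tp = sum(1 for yi, si in zip(y, s) if si >= thr and yi == 1)
        fp = sum(1 for yi, si in zip(y, s) if si >= thr and yi == 0)
        pts.append((fp / neg, tp / pos))
    auc = 0.0
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        auc += (x2 - x1) * (y1 + y2) / 2
    return auc


def oracle_aupr(y, s):
    thresholds = sorted(set(s), reverse=True)
    pos = sum(y)
    pts = [(0.0, 1.0)]
    for thr in thresholds:
        npred = sum(1 for si in s if si >= thr)
        tp = sum(1 for yi, si in zip(y, s) if si >= thr and yi == 1)
        pts.append((tp / pos, tp / npred))
    area = 0.0
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        area += (x2 - x1) * (y1 + y2) / 2
    return area


class TestEvaluate:
    def test_perfect_predictions_are_all_hundred_percent(self):
        rng = np.random.default_rng(0)
        gold = rng.integers(0, 5, size=40)
        scores = np.zeros((40, 5))
        scores[np.arange(40), gold] = 1.0
        rep = evaluate(gold, gold, scores, classes="all")
        assert rep.micro_f1 == rep.macro_f1 == 1.0
        assert rep.auc_micro == rep.auc_macro == 1.0
        assert rep.aupr_micro == rep.aupr_macro == 1.0

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n, m = 50, 5
        gold = rng.integers(0, m, size=n)
        pred = rng.integers(0, m, size=n)
        scores = rng.normal(size=(n, m))
        for classes, scope in (("all", list(range(m))),
                               ("positives_only", [1, 2, 3, 4])):
            rep = evaluate(gold, pred, scores, classes=classes)
            per, mp, mr, mf, Mp, Mr, Mf = oracle_prf(
                list(gold), list(pred), scope, m)
            assert rep.micro_precision == pytest.approx(mp, abs=1e-12)
            assert rep.micro_recall == pytest.approx(mr, abs=1e-12)
            assert rep.micro_f1 == pytest.approx(mf, abs=1e-12)
            assert rep.macro_precision == pytest.approx(Mp, abs=1e-12)
            assert rep.macro_recall == pytest.approx(Mr, abs=1e-12)
            assert rep.macro_f1 == pytest.approx(Mf, abs=1e-12)
            aucs, auprs = [], []
            for c in scope:
                y = [1 if g == c else 0 for g in gold]
                aucs.append(oracle_roc_auc(y, list(scores[:, c])))
                auprs.append(oracle_aupr(y, list(scores[:, c])))
            assert rep.auc_macro == pytest.approx(np.mean(aucs), abs=1e-12)
            assert rep.aupr_macro == pytest.approx(np.mean(auprs), abs=1e-12)
            y_flat = [1 if g == c else 0 for c in scope for g in gold]
            s_flat = [scores[i, c] for c in scope for i in range(n)]
            assert rep.auc_micro == pytest.approx(
                oracle_roc_auc(y_flat, s_flat), abs=1e-12)
            assert rep.aupr_micro == pytest.approx(
                oracle_aupr(y_flat, s_flat), abs=1e-12)

    def test_auc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=60)
        s = np.round(rng.normal(size=60), 1)      # induce ties
        fpr, tpr = roc_points(y.astype(float), s)
        assert float(np.trapezoid(tpr, fpr)) == \
            pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_per_class_prf_agrees_with_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(6)
        gold = rng.integers(0, 5, size=80)
        pred = rng.integers(0, 5, size=80)
        rep = evaluate(gold, pred, classes="all")
        p, r, f, _ = precision_recall_fscore_support(
            gold, pred, labels=range(5), zero_division=0)
        for i, name in enumerate(rep.class_names):
            assert rep.per_class[name]["precision"] == pytest.approx(p[i])
            assert rep.per_class[name]["recall"] == pytest.approx(r[i])

    def test_macro_f1_is_harmonic_of_macro_p_and_r(self):
        # asymmetric confusion where harmonic(macroP, macroR) differs from
        # the mean of per-class F1s: pin the harmonic-mean form
        gold = [0, 0, 0, 0, 1, 1]
        pred = [0, 1, 1, 1, 1, 1]
        rep = evaluate(gold, pred, classes="all",
                       class_names=("Negative", "Mechanism"))
        h = 2 * rep.macro_precision * rep.macro_recall / \
            (rep.macro_precision + rep.macro_recall)
        assert rep.macro_f1 == pytest.approx(h, abs=1e-15)
        mean_f1 = np.mean([rep.per_class[c]["f1"] for c in rep.class_names])
        assert abs(rep.macro_f1 - mean_f1) > 1e-3

    def test_all_classes_micro_precision_equals_recall(self):
        rng = np.random.default_rng(7)
        gold = rng.integers(0, 5, size=30)
        pred = rng.integers(0, 5, size=30)
        rep = evaluate(gold, pred, classes="all")
        assert rep.micro_precision == pytest.approx(rep.micro_recall)

    def test_absent_class_warns_and_scores_zero(self):
        rep = evaluate([1, 1], [1, 1], classes="all",
                       class_names=("Negative", "Mechanism", "Effect"))
        assert any("Effect" in w for w in rep.warnings_)
        assert rep.per_class["Effect"]["precision"] == 0.0

    def test_curve_table_consistent_with_curve_points(self):
        from ddikg.loss_metrics import curve_table

        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, size=40).astype(float)
        s = np.round(rng.normal(size=40), 1)
        rows = curve_table(y, s)
        assert [r["threshold"] for r in rows] == \
            sorted({float(x) for x in s}, reverse=True)
        fpr, tpr = roc_points(y, s)
        assert np.allclose([r["fpr"] for r in rows], fpr[1:], atol=1e-12)
        assert np.allclose([r["tpr"] for r in rows], tpr[1:], atol=1e-12)
        rec, prec = pr_points(y, s)
        assert np.allclose([r["precision"] for r in rows], prec[1:],
                           atol=1e-12)

    def test_report_serialises_to_json_and_tsv(self):
        rep = evaluate([0, 1, 2], [0, 1, 1], np.eye(3),
                       classes="all",
                       class_names=("Negative", "Mechanism", "Effect"))
        assert "micro" in rep.to_json()
        assert rep.to_tsv().count("\n") >= 5
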