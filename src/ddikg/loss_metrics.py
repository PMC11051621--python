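"""Multi-class focal loss with count-derived class weights, and evaluation.

The loss down-weights confidently classified instances through the modulating
factor ``(1 - p_t)^gamma`` (gamma = 2 by default) and weights classes by
``alpha``.  Two weighting readings are provided: ``printed`` sets
``alpha_i = Count_i / sum(Count)`` (proportional to class frequency), while
``inverse`` uses normalised inverse frequencies; and two focal forms:
``true_class`` (the standard focal loss, default) and ``printed_sum`` which
multiplies by the *sum* of all alphas over m — a constant rescaling when the
alphas are normalised.

Evaluation reports per-class and micro/macro precision, recall and F1 from
the multi-class confusion matrix, plus one-vs-rest AUC and AUPR.  Macro F1 is
the harmonic mean of macro precision and macro recall (not the mean of the
per-class F1s).  By the DDI-benchmark convention the Negative class is
excluded from the averages by default (``classes="positives_only"``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .corpus import CLASSES

__all__ = ["ClassWeights", "EvaluationReport", "class_weights",
           "multi_focal_loss", "evaluate", "roc_points", "pr_points",
           "curve_table"]

_EPS = 1e-12


@dataclass
class ClassWeights:
    alpha: np.ndarray
    counts: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        assert abs(self.alpha.sum() - 1.0) < 1e-9


def class_weights(counts, weighting: str = "printed") -> ClassWeights:
    """Per-class loss weights from class counts; alpha sums to one."""
    counts = np.asarray(counts, dtype=float)
    if counts.min() < 0 or counts.sum() <= 0:
        raise ValueError("counts must be non-negative with at least one positive")
    if weighting == "printed":
        alpha = counts / counts.sum()
    elif weighting == "inverse":
        inv = 1.0 / np.maximum(counts, 1.0)
        alpha = inv / inv.sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return ClassWeights(alpha=alpha, counts=counts, scheme=weighting)


def multi_focal_loss(probs, labels, alpha, gamma: float = 2.0,
                     focal_form: str = "true_class"):
    """Mean focal loss over a batch.

    `probs` may be a (n, m) autodiff Tensor (training path) or a plain array;
    the return type matches.  Probabilities at 0 are clamped to 1e-12 with a
    warning.
    """
    if focal_form not in ("true_class", "printed_sum"):
        raise ValueError(f"unknown focal_form {focal_form!r}")
    as_tensor = isinstance(probs, Tensor)
    P = probs if as_tensor else Tensor(np.asarray(probs, dtype=float))
    labels = np.asarray(labels, dtype=np.intp)
    alpha = np.asarray(alpha, dtype=float)
    n, m = P.shape
    p_t = P[np.arange(n), labels]
    if np.any(p_t.data <= 0.0):
        warnings.warn("true-class probability of 0 clamped to 1e-12",
                      RuntimeWarning, stacklevel=2)
    p_t = p_t.clamp_min(_EPS)
    focal = (1.0 - p_t) ** gamma * (-p_t.log())
    if focal_form == "true_class":
        per_instance = Tensor(alpha[labels]) * focal
    else:  # the printed sum-over-classes form: -(sum_i alpha_i)(1-p_t)^g log p_t / m
        per_instance = focal * (float(alpha.sum()) / m)
    loss = per_instance.mean()
    return loss if as_tensor else loss.item()


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    class_names: list[str]
    scope: list[str]                       # classes included in the averages
    per_class: dict[str, dict[str, float]]  # name -> tp/fp/fn/precision/recall/f1
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    auc_micro: float | None = None
    auc_macro: float | None = None
    aupr_micro: float | None = None
    aupr_macro: float | None = None
    warnings_: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": self.class_names, "averaging_scope": self.scope,
            "per_class": self.per_class,
            "micro": {"precision": self.micro_precision, "recall": self.micro_recall,
                      "f1": self.micro_f1, "auc": self.auc_micro,
                      "aupr": self.aupr_micro},
            "macro": {"precision": self.macro_precision, "recall": self.macro_recall,
                      "f1": self.macro_f1, "auc": self.auc_macro,
                      "aupr": self.aupr_macro},
            "warnings": self.warnings_,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        lines = ["class\ttp\tfp\tfn\tprecision\trecall\tf1"]
        for name, row in self.per_class.items():
            lines.append(f"{name}\t{row['tp']:.0f}\t{row['fp']:.0f}\t{row['fn']:.0f}"
                         f"\t{row['precision']:.6f}\t{row['recall']:.6f}"
                         f"\t{row['f1']:.6f}")
        for tag, p, r, f1 in (("micro", self.micro_precision, self.micro_recall,
                               self.micro_f1),
                              ("macro", self.macro_precision, self.macro_recall,
                               self.macro_f1)):
            lines.append(f"{tag}\t\t\t\t{p:.6f}\t{r:.6f}\t{f1:.6f}")
        return "\n".join(lines) + "\n"


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def _harmonic(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def roc_points(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve (FPR, TPR) with tied scores grouped; includes (0,0) and (1,1)."""
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    pos, neg = y.sum(), len(y) - y.sum()
    boundaries = np.flatnonzero(np.diff(s)) + 1
    tp = np.concatenate([[0], np.cumsum(y)[np.append(boundaries - 1, len(y) - 1)]])
    fp = np.concatenate([[0], np.cumsum(1 - y)[np.append(boundaries - 1, len(y) - 1)]])
    fpr = fp / neg if neg > 0 else np.zeros_like(fp, dtype=float)
    tpr = tp / pos if pos > 0 else np.zeros_like(tp, dtype=float)
    return fpr, tpr


def pr_points(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PR curve (recall, precision) over descending-score tie groups,
    anchored at (0, 1)."""
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    pos = y.sum()
    boundaries = np.flatnonzero(np.diff(s)) + 1
    ends = np.append(boundaries - 1, len(y) - 1)
    tp = np.cumsum(y)[ends]
    n_pred = ends + 1
    recall = np.concatenate([[0.0], tp / pos]) if pos > 0 else \
        np.zeros(len(ends) + 1)
    precision = np.concatenate([[1.0], tp / n_pred])
    return recall, precision


def _auc_trapezoid(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.trapezoid(y, x))


def curve_table(y, s) -> list[dict[str, float]]:
    """Per-threshold operating points for one binary score vector.

    One row per distinct score value (descending): the threshold and the
    precision, recall, TPR and FPR of predicting positive at score >=
    threshold.  Suitable for dumping ROC/PR curves as a flat TSV.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    pos, neg = y.sum(), len(y) - y.sum()
    rows = []
    for thr in np.unique(s)[::-1]:
        mask = s >= thr
        tp = float(y[mask].sum())
        fp = float(mask.sum() - tp)
        rows.append({"threshold": float(thr),
                     "precision": _safe_div(tp, tp + fp),
                     "recall": _safe_div(tp, pos),
                     "tpr": _safe_div(tp, pos),
                     "fpr": _safe_div(fp, neg)})
    return rows


def evaluate(gold, predicted, scores=None, classes: str = "positives_only",
             class_names: tuple[str, ...] = CLASSES) -> EvaluationReport:
    """Full evaluation report from label vectors and (optionally) class scores.

    `gold` and `predicted` are integer class indices (or label strings);
    `scores` is an (n, m) matrix for the one-vs-rest AUC/AUPR metrics.
    """
    names = list(class_names)
    to_idx = {c: i for i, c in enumerate(names)}
    gold = np.asarray([to_idx[g] if isinstance(g, str) else int(g) for g in gold])
    predicted = np.asarray([to_idx[p] if isinstance(p, str) else int(p)
                            for p in predicted])
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted label vectors differ in length")
    if classes == "positives_only":
        scope = [i for i, c in enumerate(names) if c != "Negative"]
    elif classes == "all":
        scope = list(range(len(names)))
    else:
        raise ValueError(f"unknown averaging scope {classes!r}")

    warns: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    tp = np.zeros(len(names)); fp = np.zeros(len(names)); fn = np.zeros(len(names))
    for i, name in enumerate(names):
        tp[i] = np.sum((gold == i) & (predicted == i))
        fp[i] = np.sum((gold != i) & (predicted == i))
        fn[i] = np.sum((gold == i) & (predicted != i))
        if tp[i] + fp[i] + fn[i] == 0:
            warns.append(f"class {name!r} absent from gold and predictions; "
                         "precision/recall set to 0")
        p_i = _safe_div(tp[i], tp[i] + fp[i])
        r_i = _safe_div(tp[i], tp[i] + fn[i])
        per_class[name] = {"tp": float(tp[i]), "fp": float(fp[i]),
                           "fn": float(fn[i]), "precision": p_i, "recall": r_i,
                           "f1": _harmonic(p_i, r_i)}

    sel = np.asarray(scope, dtype=int)
    micro_p = _safe_div(tp[sel].sum(), tp[sel].sum() + fp[sel].sum())
    micro_r = _safe_div(tp[sel].sum(), tp[sel].sum() + fn[sel].sum())
    macro_p = float(np.mean([per_class[names[i]]["precision"] for i in sel]))
    macro_r = float(np.mean([per_class[names[i]]["recall"] for i in sel]))

    report = EvaluationReport(
        class_names=names, scope=[names[i] for i in sel], per_class=per_class,
        micro_precision=micro_p, micro_recall=micro_r,
        micro_f1=_harmonic(micro_p, micro_r),
        macro_precision=macro_p, macro_recall=macro_r,
        macro_f1=_harmonic(macro_p, macro_r), warnings_=warns)

    if scores is not None:
        S = np.asarray(scores, dtype=float)
        aucs, auprs = [], []
        flat_y, flat_s = [], []
        for i in sel:
            y = (gold == i).astype(float)
            flat_y.append(y); flat_s.append(S[:, i])
            if y.sum() == 0 or y.sum() == len(y):
                warns.append(f"class {names[i]!r} has no positives or no "
                             "negatives; skipped in macro AUC/AUPR")
                continue
            fpr, tpr = roc_points(y, S[:, i])
            aucs.append(_auc_trapezoid(fpr, tpr))
            rec, prec = pr_points(y, S[:, i])
            auprs.append(_auc_trapezoid(rec, prec))
        y_all = np.concatenate(flat_y); s_all = np.concatenate(flat_s)
        if 0 < y_all.sum() < len(y_all):
            fpr, tpr = roc_points(y_all, s_all)
            report.auc_micro = _auc_trapezoid(fpr, tpr)
            rec, prec = pr_points(y_all, s_all)
            report.aupr_micro = _auc_trapezoid(rec, prec)
        report.auc_macro = float(np.mean(aucs)) if aucs else None
        report.aupr_macro = float(np.mean(auprs)) if auprs else None
    return report
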