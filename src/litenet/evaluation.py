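"""Confusion matrices, classification metrics, multiclass AUC and its rating.

Conventions
-----------
* Confusion matrices are 5×5 with **rows = predicted, columns = true** class.
* The binary collapse maps N → "normal" and {S, V, F, Q} → "arrhythmia", with
  TP = predicted-normal ∧ true-normal (so a beat predicted normal whose true
  label is an arrhythmia counts as a false positive).
* ACC = (TP+TN)/(TP+FN+FP+TN); precision = TP/(TP+FP); recall = TP/(TP+FN);
  F1 is their harmonic mean.  A zero denominator yields an undefined flag
  (``None``), never a NaN.
* Multiclass aggregation is **macro** (unweighted mean over classes with
  defined metrics); overall accuracy is trace/total.  Micro-averaged and
  binary-collapsed numbers are emitted alongside so any convention can be
  compared.
* AUC is the rank-based (Mann–Whitney) one-vs-rest statistic with ties
  counted 0.5, macro-averaged over classes that have at least one positive
  and one negative example.
* AUC ratings: [0.9, 1.0] Excellent, [0.8, 0.9) Good, [0.7, 0.8) Fair,
  [0.6, 0.7) Poor, below 0.6 Failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .signal_io import AAMI_CLASSES, CLASS_TO_INDEX


@dataclass
class ConfusionMatrix:
    """Integer count matrix; ``counts[p][t]`` = predicted p, true t."""

    counts: np.ndarray
    labels: tuple[str, ...] = AAMI_CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, pred, true, labels: tuple[str, ...] = AAMI_CLASSES):
        pred = np.asarray(pred)
        true = np.asarray(true)
        if pred.shape != true.shape:
            raise ValueError("pred and true must have equal length")
        to_idx = {lab: i for i, lab in enumerate(labels)}
        k = len(labels)
        counts = np.zeros((k, k), dtype=np.int64)
        for p, t in zip(pred, true):
            pi = p if isinstance(p, (int, np.integer)) else to_idx[p]
            ti = t if isinstance(t, (int, np.integer)) else to_idx[t]
            counts[pi][ti] += 1
        return cls(counts, labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def binary_collapse(self) -> dict[str, int]:
        """Collapse to normal-vs-arrhythmia counts (N is the positive class)."""
        n = CLASS_TO_INDEX["N"]
        c = self.counts
        tp = int(c[n, n])
        fp = int(c[n, :].sum() - c[n, n])     # predicted normal, true arrhythmia
        fn = int(c[:, n].sum() - c[n, n])     # predicted arrhythmia, true normal
        tn = int(self.total - tp - fp - fn)
        return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}

    def one_vs_rest(self, class_index: int) -> dict[str, int]:
        c = self.counts
        tp = int(c[class_index, class_index])
        fp = int(c[class_index, :].sum() - tp)
        fn = int(c[:, class_index].sum() - tp)
        tn = int(self.total - tp - fp - fn)
        return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def basic_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float | None]:
    """Accuracy, precision, recall and F1 from the four confusion counts.

    Exact rational evaluation; any zero denominator gives ``None`` for the
    affected metric (all-zero counts give an all-``None`` report).
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total else None
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"acc": acc, "precision": precision, "recall": recall, "f1": f1}


def multiclass_summary(cm: ConfusionMatrix) -> dict:
    """Per-class one-vs-rest metrics plus macro means and overall accuracy."""
    per_class: dict[str, dict[str, float | None]] = {}
    for i, lab in enumerate(cm.labels):
        per_class[lab] = basic_metrics(**cm.one_vs_rest(i))
    total = cm.total
    out = {
        "per_class": per_class,
        "accuracy": float(np.trace(cm.counts)) / total if total else None,
    }
    for metric in ("precision", "recall", "f1"):
        vals = [m[metric] for m in per_class.values() if m[metric] is not None]
        out[f"macro_{metric}"] = float(np.mean(vals)) if vals else None
    return out


def auc_score(scores: np.ndarray, true_labels: np.ndarray) -> tuple[float | None, dict]:
    """Macro one-vs-rest rank AUC.

    ``scores`` is an (n, k) matrix of class probabilities (rows sum to 1
    within 1e-6); ``true_labels`` holds integer class indices.  Per class,
    AUC = (Σ ranks of positives − n₊(n₊+1)/2) / (n₊·n₋) with average ranks
    for ties.  Classes lacking positives or negatives are excluded with a
    warning; returns ``(macro_auc, per_class_auc)``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    true_labels = np.asarray(true_labels)
    if scores.ndim != 2 or scores.shape[0] != len(true_labels):
        raise ValueError("scores must be (n, k) aligned with true_labels")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("score rows must sum to 1")
    per_class: dict[int, float] = {}
    for i in range(scores.shape[1]):
        pos = true_labels == i
        n_pos = int(pos.sum())
        n_neg = len(true_labels) - n_pos
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"class {i} has no positives or no negatives; excluded from AUC")
            continue
        ranks = rankdata(scores[:, i])  # average ranks → ties count 0.5
        per_class[i] = float(
            (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        )
    macro = float(np.mean(list(per_class.values()))) if per_class else None
    return macro, per_class


def auc_rating(auc: float) -> str:
    """Map an AUC value to its qualitative rating band.

    Bands are half-open on the left edge with 1.0 included in Excellent;
    anything below 0.6 — including worse-than-chance — is Failure.
    """
    if not (0.0 <= auc <= 1.0):
        raise ValueError(f"AUC must lie in [0, 1], got {auc}")
    if auc >= 0.9:
        return "Excellent"
    if auc >= 0.8:
        return "Good"
    if auc >= 0.7:
        return "Fair"
    if auc >= 0.6:
        return "Poor"
    return "Failure"


@dataclass
class EvaluationReport:
    """Everything one evaluation produces, JSON-serializable via to_dict()."""

    confusion: ConfusionMatrix | None
    accuracy: float | None
    per_class: dict | None
    macro_precision: float | None
    macro_recall: float | None
    macro_f1: float | None
    macro_auc: float | None
    auc_rating: str | None
    binary: dict | None = None
    pc: int | None = None
    total_params: int | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
            "auc_rating": self.auc_rating,
            "per_class": self.per_class,
            "binary": self.binary,
            "pc": self.pc,
            "total_params": self.total_params,
        }
        if self.confusion is not None:
            d["confusion"] = self.confusion.counts.tolist()
            d["confusion_labels"] = list(self.confusion.labels)
        return d


def evaluate(pred, true, scores: np.ndarray | None = None, ledger=None) -> EvaluationReport:
    """Full evaluation of one prediction set.

    ``pred``/``true`` are labels (strings or integer indices); ``scores`` an
    optional probability matrix enabling AUC; ``ledger`` an optional
    :class:`~litenet.network.ParameterLedger` whose totals are attached.
    """
    cm = ConfusionMatrix.from_labels(pred, true)
    summary = multiclass_summary(cm)
    binary = basic_metrics(**cm.binary_collapse())
    macro_auc = rating = None
    if scores is not None:
        true_idx = np.asarray(
            [t if isinstance(t, (int, np.integer)) else CLASS_TO_INDEX[t] for t in np.asarray(true)]
        )
        macro_auc, _ = auc_score(scores, true_idx)
        rating = auc_rating(macro_auc) if macro_auc is not None else None
    return EvaluationReport(
        confusion=cm,
        accuracy=summary["accuracy"],
        per_class=summary["per_class"],
        macro_precision=summary["macro_precision"],
        macro_recall=summary["macro_recall"],
        macro_f1=summary["macro_f1"],
        macro_auc=macro_auc,
        auc_rating=rating,
        binary=binary,
        pc=ledger.pc if ledger is not None else None,
        total_params=ledger.total if ledger is not None else None,
    )


def mean_report(reports: list[EvaluationReport]) -> EvaluationReport:
    """Arithmetic mean of per-fold aggregate metrics; confusions are summed."""
    if not reports:
        raise ValueError("no reports to average")

    def _mean(attr: str) -> float | None:
        vals = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else None

    counts = sum(r.confusion.counts for r in reports if r.confusion is not None)
    macro_auc = _mean("macro_auc")
    return EvaluationReport(
        confusion=ConfusionMatrix(counts) if reports[0].confusion is not None else None,
        accuracy=_mean("accuracy"),
        per_class=None,
        macro_precision=_mean("macro_precision"),
        macro_recall=_mean("macro_recall"),
        macro_f1=_mean("macro_f1"),
        macro_auc=macro_auc,
        auc_rating=auc_rating(macro_auc) if macro_auc is not None else None,
        binary=None,
        pc=reports[0].pc,
        total_params=reports[0].total_params,
    )
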