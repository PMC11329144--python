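"""Cross-validated evaluation: metrics, ROC/AUC, folds, and the printed-table audit.

The abnormal (stenotic) class is the positive class throughout.  Metrics
follow the standard confusion-matrix definitions:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

AUC is the trapezoidal integral of the ROC curve over score thresholds, which
equals the Mann–Whitney pair statistic (ties counted one half).

``reconstruct_confusion`` inverts 4-decimal printed metrics back to integer
confusion matrices by exhaustive search — an audit tool for published results
tables, which also detects internally inconsistent rows.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .labeling import LabeledRecording

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "compute_metrics",
    "auc_roc",
    "stratified_folds",
    "reconstruct_confusion",
    "mcnemar_exact",
    "run_experiment",
    "ExperimentReport",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    confusion: ConfusionMatrix

    def rounded(self) -> dict[str, float]:
        """4-decimal rendering used in results tables."""
        return {
            k: float(round_half_up(getattr(self, k), 4))
            for k in ("accuracy", "precision", "recall", "f1", "auc")
            if np.isfinite(getattr(self, k))
        }


def round_half_up(x: float, places: int) -> Decimal:
    return Decimal(repr(float(x))).quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", RuntimeWarning)
        return float("nan")
    return num / den


def compute_metrics(
    cm: ConfusionMatrix,
    scores: list[tuple[float, int]] | None = None,
) -> MetricsReport:
    """All table metrics from a confusion matrix (and scores, for AUC).

    Ratios with a zero denominator are reported as NaN with a warning, never
    silently zero.  AUC is NaN unless ``scores`` — pairs of (abnormal score,
    true label) — are given.
    """
    accuracy = _safe_ratio(cm.tp + cm.tn, cm.total, "accuracy")
    precision = _safe_ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = _safe_ratio(cm.tp, cm.tp + cm.fn, "recall")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        warnings.warn("F1 undefined; reporting NaN", RuntimeWarning)
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    auc = auc_roc(scores) if scores is not None else float("nan")
    return MetricsReport(accuracy, precision, recall, f1, auc, cm)


def auc_roc(scores: list[tuple[float, int]]) -> float:
    """Area under the ROC curve by trapezoidal integration over thresholds.

    Scores with tied values are grouped so the result equals the
    Mann–Whitney statistic with ties counted one half.  Raises if only one
    class is present.
    """
    s = np.asarray([x for x, _ in scores], dtype=np.float64)
    y = np.asarray([lab for _, lab in scores], dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    tps, fps = [0], [0]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # sweep a tie group at once
            tp += int(y[j] == 1)
            fp += int(y[j] == 0)
            j += 1
        tps.append(tp)
        fps.append(fp)
        i = j
    tpr = np.asarray(tps) / n_pos
    fpr = np.asarray(fps) / n_neg
    return float(np.trapezoid(tpr, fpr))


def stratified_folds(
    labeled: list[LabeledRecording], k: int = 5, seed: int = 0
) -> np.ndarray:
    """Stratified k-fold partition of the labeled recordings.

    Returns a fold id per recording.  Each fold holds a class proportion
    within one recording of the global proportion.  Recordings that are
    unlabeled raise — only normal/abnormal recordings can be cross-validated.
    """
    labels = [lr.label for lr in labeled]
    if "unlabeled" in labels:
        raise ValueError("unlabeled recordings cannot be cross-validated; filter them out first")
    y = np.asarray([1 if lab == "abnormal" else 0 for lab in labels])
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(f"need >= {k} recordings of each class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_id = np.empty(len(labeled), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_id[test_idx] = f
    return fold_id


def _matches_printed(value: float, printed: float, places: int = 4) -> bool:
    """True if ``value`` renders as ``printed`` by round-half-up or truncation."""
    q = Decimal(10) ** -places
    printed_d = Decimal(repr(printed)).quantize(q)
    if round_half_up(value, places) == printed_d:
        return True
    truncated = Decimal(repr(float(value))).quantize(q, rounding="ROUND_DOWN")
    return truncated == printed_d


def reconstruct_confusion(
    accuracy: float,
    precision: float,
    recall: float,
    n_pos: int,
    n_neg: int,
) -> list[ConfusionMatrix]:
    """Invert printed 4-decimal metrics to integer confusion matrices.

    Exhaustive search over TP in [0, n_pos] and FP in [0, n_neg]; a candidate
    matches if each of its three metrics renders to the printed value by
    round-half-up or truncation at 4 decimals (published tables use both).
    Raises ``ValueError`` if no matrix is consistent; a result list longer
    than one flags an ambiguous row.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes must be non-empty")
    out = []
    total = n_pos + n_neg
    for tp in range(n_pos + 1):
        rec = tp / n_pos
        if not _matches_printed(rec, recall):
            continue
        for fp in range(n_neg + 1):
            acc = (tp + (n_neg - fp)) / total
            if not _matches_printed(acc, accuracy):
                continue
            if tp + fp == 0 or not _matches_printed(tp / (tp + fp), precision):
                continue
            out.append(ConfusionMatrix(tp=tp, fp=fp, fn=n_pos - tp, tn=n_neg - fp))
    if not out:
        raise ValueError(
            "inconsistent printed row: no integer confusion matrix on "
            f"{n_pos} positives / {n_neg} negatives renders as "
            f"(acc={accuracy}, prec={precision}, rec={recall})"
        )
    if len(out) > 1:
        warnings.warn(f"printed row is ambiguous: {len(out)} matrices match", RuntimeWarning)
    return out


def mcnemar_exact(correct_a: np.ndarray, correct_b: np.ndarray) -> float:
    """Exact McNemar p-value on paired per-recording correctness of two arms."""
    correct_a = np.asarray(correct_a, dtype=bool)
    correct_b = np.asarray(correct_b, dtype=bool)
    if correct_a.shape != correct_b.shape:
        raise ValueError("paired vectors must have equal length")
    table = np.array(
        [
            [np.sum(correct_a & correct_b), np.sum(correct_a & ~correct_b)],
            [np.sum(~correct_a & correct_b), np.sum(~correct_a & ~correct_b)],
        ]
    )
    if table[0, 1] + table[1, 0] == 0:
        return 1.0  # identical predictions: no discordant pairs
    return float(_sm_mcnemar(table, exact=True).pvalue)


@dataclass
class ArmResult:
    metrics: MetricsReport
    per_fold: list[MetricsReport]
    scores: np.ndarray       # abnormal-class score per labeled recording
    predictions: np.ndarray  # 0/1 per labeled recording
    y_true: np.ndarray


@dataclass
class ExperimentReport:
    arms: dict[str, ArmResult]
    pairwise_p: dict[tuple[str, str], float]
    fold_id: np.ndarray

    def table(self) -> pd.DataFrame:
        rows = []
        for name, arm in self.arms.items():
            row = {"method": name}
            row.update(arm.metrics.rounded())
            rows.append(row)
        return pd.DataFrame(rows)


def run_experiment(
    labeled: list[LabeledRecording],
    train_arm,
    featurize,
    arms: list[str],
    k: int = 5,
    seed: int = 0,
) -> ExperimentReport:
    """Stratified k-fold cross-validation of one or more training arms.

    ``train_arm(arm_name, train_records, fold_seed)`` must return a trained
    model exposing ``classify`` (two sigmoid scores) and ``predict_label``;
    ``featurize(labeled_recording)`` yields its model input.  Each held-out
    recording is scored individually, so every labeled recording is scored
    exactly once per arm; metrics come from the pooled confusion matrix, the
    abnormal-class score drives the ROC, and arms are compared pairwise with
    the exact McNemar test on per-recording correctness.
    """
    fold_id = stratified_folds(labeled, k=k, seed=seed)
    y_true = np.asarray([1 if lr.label == "abnormal" else 0 for lr in labeled])

    results: dict[str, ArmResult] = {}
    for arm in arms:
        scores = np.full(len(labeled), np.nan)
        preds = np.full(len(labeled), -1, dtype=int)
        for f in range(k):
            train_records = [lr for lr, fid in zip(labeled, fold_id) if fid != f]
            model = train_arm(arm, train_records, seed * 1000 + f)
            test_idx = np.flatnonzero(fold_id == f)
            # each held-out recording is scored individually (its prediction
            # depends only on its own spectrogram); the forwards are batched
            both = model.classify(np.stack([featurize(labeled[i]) for i in test_idx]))
            scores[test_idx] = both[:, 1]
            preds[test_idx] = model.predict_label(both)
        if np.any(np.isnan(scores)) or np.any(preds < 0):
            raise RuntimeError("cross-validation failed to score every recording once")
        cm = ConfusionMatrix.from_predictions(y_true, preds)
        pooled = compute_metrics(cm, list(zip(scores.tolist(), y_true.tolist())))
        per_fold = []
        for f in range(k):
            test_idx = np.flatnonzero(fold_id == f)
            fold_cm = ConfusionMatrix.from_predictions(y_true[test_idx], preds[test_idx])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                per_fold.append(compute_metrics(fold_cm))
        results[arm] = ArmResult(pooled, per_fold, scores, preds, y_true)

    pairwise = {}
    for a, b in itertools.combinations(arms, 2):
        pairwise[(a, b)] = mcnemar_exact(
            results[a].predictions == y_true, results[b].predictions == y_true
        )
    return ExperimentReport(results, pairwise, fold_id)
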