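"""Classification evaluation: confusion matrices, per-class metrics, run comparisons.

The study protocol repeats every training several times and reports, per
configuration, the distribution of overall accuracies, the mean confusion
matrix over runs (in percent of all frames), and per-class one-vs-rest
sensitivity / specificity / precision / F-score.  Configurations are
compared with the two-sided Wilcoxon rank-sum test, the accuracy of each
repeat being one sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .datasets import ALL_LABELS
from .exceptions import EvaluationError, SchemaError

METRIC_NAMES = ("sensitivity", "specificity", "precision", "f_score")


@dataclass(frozen=True)
class ConfusionMatrix:
    """True-class x predicted-class counts over a fixed label set."""

    counts: np.ndarray
    labels: tuple[int, ...] = ALL_LABELS

    def __post_init__(self) -> None:
        C = np.asarray(self.counts)
        k = len(self.labels)
        if C.shape != (k, k):
            raise SchemaError(f"counts must be ({k}, {k}), got {C.shape}")
        if np.any(C < 0):
            raise SchemaError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", C.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def percent(self) -> np.ndarray:
        """Cells as percent of all frames; sums to 100."""
        if self.total == 0:
            raise EvaluationError("empty confusion matrix")
        return 100.0 * self.counts / self.total

    def accuracy(self) -> float:
        if self.total == 0:
            raise EvaluationError("empty confusion matrix")
        return float(np.trace(self.counts) / self.total)

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        data = self.percent() if percent else self.counts
        idx = pd.Index(self.labels, name="true")
        cols = pd.Index(self.labels, name="predicted")
        return pd.DataFrame(data, index=idx, columns=cols)


def confusion_matrix(
    truth, predicted, labels: tuple[int, ...] = ALL_LABELS
) -> ConfusionMatrix:
    """Count-based confusion matrix; entry (i, j) = true i predicted j."""
    truth = np.ravel(np.asarray(truth))
    predicted = np.ravel(np.asarray(predicted))
    if truth.shape != predicted.shape:
        raise SchemaError(
            f"truth and predicted lengths differ: {truth.shape} vs {predicted.shape}"
        )
    counts = _sk_confusion(truth, predicted, labels=list(labels))
    return ConfusionMatrix(counts, tuple(labels))


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest metrics per class.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision =
    TP/(TP+FP), F-score = harmonic mean of precision and sensitivity.
    Ratios with a zero denominator are reported as NaN (absent), not 0.
    """
    C = cm.counts
    if C.sum() == 0:
        raise EvaluationError("cannot compute metrics of an empty matrix")
    total = C.sum()
    tp = np.diag(C).astype(float)
    fn = C.sum(axis=1) - tp
    fp = C.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def _ratio(num, den):
        return np.where(den > 0, num / np.where(den == 0, 1.0, den), np.nan)

    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    ps = prec + sens
    f = np.where(
        np.isnan(prec) | np.isnan(sens) | (ps == 0),
        np.nan,
        2.0 * prec * sens / np.where(ps == 0, 1.0, ps),
    )
    return pd.DataFrame(
        {"sensitivity": sens, "specificity": spec, "precision": prec, "f_score": f},
        index=pd.Index(cm.labels, name="class"),
    )


@dataclass(frozen=True)
class MeanConfusion:
    """Element-wise mean and SD of confusion matrices over repeated runs."""

    mean: np.ndarray
    sd: np.ndarray
    labels: tuple[int, ...]
    percent: bool


def mean_confusion(cms: list[ConfusionMatrix], percent: bool = True) -> MeanConfusion:
    """Average confusion matrices over runs, element-wise.

    With ``percent=True`` (the reporting convention used for repeated
    simulations) each matrix is first normalized to percent of its own
    total, so the mean still sums to 100.
    """
    if not cms:
        raise EvaluationError("need at least one confusion matrix")
    labels = cms[0].labels
    if any(cm.labels != labels for cm in cms):
        raise EvaluationError("confusion matrices have mismatched label sets")
    stack = np.stack([cm.percent() if percent else cm.counts.astype(float) for cm in cms])
    return MeanConfusion(stack.mean(axis=0), stack.std(axis=0), labels, percent)


def summarize_runs(accuracies) -> dict:
    """Mean ± SD summary of per-run overall accuracies."""
    acc = np.asarray(list(accuracies), dtype=float)
    if acc.size == 0:
        raise EvaluationError("no runs to summarize")
    if np.any((acc < 0) | (acc > 1)):
        raise EvaluationError("accuracies must lie in [0, 1]")
    return {"n_runs": int(acc.size), "mean": float(acc.mean()), "sd": float(acc.std())}


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    pvalue: float
    significant: bool
    alpha: float


def rank_sum_compare(a, b, alpha: float = 0.05) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test between two run distributions."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise EvaluationError("need at least 3 samples per distribution")
    stat, p = stats.ranksums(a, b)
    return RankSumResult(float(stat), float(p), bool(p <= alpha), alpha)
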