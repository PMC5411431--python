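"""Decoder evaluation: accuracy, F1, ROC-AUC, rank tables and the
Friedman statistic.

Error is the positive class throughout.  AUC is computed by pairwise
concordance of the posteriors (ties counted one half), which equals the
trapezoidal area under the ROC curve.  Classifier comparison follows the
nonparametric recipe: rank K classifiers on each of N metrics (1 = best,
mid-ranks on ties), average the ranks per classifier, and test the
no-difference null with

    chi2_F = 12 N / (K (K + 1)) * (sum_j R_j^2 - K (K + 1)^2 / 4)

on K - 1 degrees of freedom.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


class AUCUndefinedError(ValueError):
    """AUC requested with only one class present."""


@dataclass
class MetricsReport:
    """Headline metrics of one prediction set (Error positive)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    n_trials: int
    per_subject: dict[str, "MetricsReport"] | None = None

    def as_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "precision": self.precision,
             "recall": self.recall, "f1": self.f1, "auc": self.auc,
             "n_trials": self.n_trials}
        if self.per_subject:
            d["per_subject"] = {k: v.as_dict()
                                for k, v in self.per_subject.items()}
        return d


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Pairwise-concordance AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Computed via mid-ranks, which is exactly the normalised count of
    concordant positive/negative pairs with ties worth one half.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise AUCUndefinedError("AUC needs both classes present")
    r = rankdata(s)
    return (r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def score(y_true: np.ndarray, posterior: np.ndarray,
          threshold: float = 0.5,
          subject_ids: list[str] | None = None) -> MetricsReport:
    """Accuracy, precision, recall, F1 and AUC of one prediction set.

    F1 is the harmonic mean of precision and recall (0 by convention
    when both are 0).  With a single class in ``y_true`` the AUC is
    reported as None; the other metrics are still returned.
    """
    y = np.asarray(y_true).astype(int)
    p = np.asarray(posterior, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError("labels and posteriors must align")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    acc = (tp + tn) / y.size
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    try:
        auc = auc_score(y, p)
    except AUCUndefinedError:
        auc = None
    per_subject = None
    if subject_ids is not None:
        sid = np.asarray(subject_ids)
        per_subject = {
            s: score(y[sid == s], p[sid == s], threshold)
            for s in sorted(set(subject_ids))
        }
    return MetricsReport(accuracy=acc, precision=prec, recall=rec, f1=f1,
                         auc=auc, n_trials=y.size, per_subject=per_subject)


@dataclass
class RankTable:
    """Per-metric ranks (1 = best) of K classifiers and their averages."""

    classifiers: tuple[str, ...]
    metrics: tuple[str, ...]
    ranks: np.ndarray          # (K, N)
    average_ranks: np.ndarray  # (K,)

    @property
    def K(self) -> int:
        return len(self.classifiers)

    @property
    def N(self) -> int:
        return len(self.metrics)


def rank_classifiers(values: np.ndarray,
                     classifiers: tuple[str, ...] | None = None,
                     metrics: tuple[str, ...] | None = None,
                     higher_is_better: np.ndarray | bool = True) -> RankTable:
    """Rank K classifiers on each of N metric columns (mid-ranks on ties)."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 2:
        raise ValueError("values must be a (K, N) matrix")
    K, N = v.shape
    hib = np.broadcast_to(np.asarray(higher_is_better, bool), (N,))
    ranks = np.empty_like(v)
    for j in range(N):
        col = -v[:, j] if hib[j] else v[:, j]
        ranks[:, j] = rankdata(col)
    return RankTable(
        classifiers=classifiers or tuple(f"clf{i + 1}" for i in range(K)),
        metrics=metrics or tuple(f"metric{j + 1}" for j in range(N)),
        ranks=ranks, average_ranks=ranks.mean(axis=1))


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    reject_null: bool | None = None


def friedman_stat(average_ranks: np.ndarray | RankTable,
                  n_metrics: int | None = None,
                  critical_value: float | None = None) -> FriedmanResult:
    """Friedman chi-square from average ranks R_j over N metric columns.

    Accepts either a :class:`RankTable` (N inferred) or a length-K array
    of average ranks together with ``n_metrics``.  When a critical value
    is supplied the null (all classifiers equivalent) is rejected iff
    chi2 exceeds it.
    """
    if isinstance(average_ranks, RankTable):
        R = average_ranks.average_ranks
        N = average_ranks.N
    else:
        R = np.asarray(average_ranks, dtype=np.float64)
        if n_metrics is None:
            raise ValueError("n_metrics is required with a raw rank array")
        N = int(n_metrics)
    K = R.size
    if K < 2 or N < 1:
        raise ValueError("need K >= 2 classifiers and N >= 1 metrics")
    chi2 = 12.0 * N / (K * (K + 1)) * (np.sum(R ** 2) - K * (K + 1) ** 2 / 4.0)
    reject = None if critical_value is None else bool(chi2 > critical_value)
    return FriedmanResult(chi2=float(chi2), df=K - 1, reject_null=reject)
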