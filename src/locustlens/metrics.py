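"""Binary classification metrics: confusion counts, accuracy / precision /
recall / F1, rank-based AUC, and per-country breakdowns.

Conventions: the presence class ("yes" = 1) is positive.  Zero-denominator
metrics return 0 (with a warning) so per-country tables always render.  AUC
is the Mann–Whitney statistic over the classifier's positive scores —
P(score_pos > score_neg) + 1/2 P(tie), exact over all positive×negative
pairs — which is well defined even though a K-NN's scores take at most k+1
distinct values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ContractError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None  # None when undefined (single truth class)
    counts: ConfusionCounts | None = None
    mean_fit_s: float | None = None
    mean_predict_s: float | None = None
    per_country: dict[str, "MetricsReport"] | None = None

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }
        if self.counts is not None:
            out["confusion"] = {
                "tp": self.counts.tp, "tn": self.counts.tn,
                "fp": self.counts.fp, "fn": self.counts.fn,
            }
        if self.mean_fit_s is not None:
            out["mean_fit_s"] = self.mean_fit_s
        if self.mean_predict_s is not None:
            out["mean_predict_s"] = self.mean_predict_s
        if self.per_country is not None:
            out["per_country"] = {
                c: r.to_dict() for c, r in self.per_country.items()
            }
        return out


def confusion(records: pd.DataFrame) -> ConfusionCounts:
    """Exact confusion counts from a frame with y_true / y_pred in {0, 1}."""
    if len(records) == 0:
        raise ContractError("no records to evaluate")
    t = records["y_true"].to_numpy().astype(int)
    p = records["y_pred"].to_numpy().astype(int)
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} has zero denominator; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts, average: str = "micro") -> MetricsReport:
    """Accuracy = (TP+TN)/N, precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R); zero denominators yield 0.

    ``average="macro"`` reports class-averaged precision/recall/F1 (each
    class in turn treated as positive) instead of the positive-class values.
    """
    if c.total == 0:
        raise ContractError("empty confusion counts")
    accuracy = (c.tp + c.tn) / c.total
    if average == "micro":
        precision = _ratio(c.tp, c.tp + c.fp, "precision")
        recall = _ratio(c.tp, c.tp + c.fn, "recall")
        f1 = _ratio(2 * precision * recall, precision + recall, "F1")
    elif average == "macro":
        p1 = _ratio(c.tp, c.tp + c.fp, "precision(+)")
        p0 = _ratio(c.tn, c.tn + c.fn, "precision(-)")
        r1 = _ratio(c.tp, c.tp + c.fn, "recall(+)")
        r0 = _ratio(c.tn, c.tn + c.fp, "recall(-)")
        precision = 0.5 * (p1 + p0)
        recall = 0.5 * (r1 + r0)
        f11 = _ratio(2 * p1 * r1, p1 + r1, "F1(+)")
        f10 = _ratio(2 * p0 * r0, p0 + r0, "F1(-)")
        f1 = 0.5 * (f11 + f10)
    else:
        raise ContractError(f"unknown average {average!r}")
    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1, counts=c
    )


def auc(records: pd.DataFrame) -> float:
    """Mann–Whitney AUC from positive scores, exact with half-credit ties.

    Uses midranks: AUC = (R+ − n+(n+ + 1)/2) / (n+ · n−) where R+ is the
    rank-sum of positive-class scores, identical to exhaustive enumeration
    of all positive×negative pairs.
    """
    t = records["y_true"].to_numpy().astype(int)
    s = records["score"].to_numpy().astype(float)
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: a single truth class")
    ranks = rankdata(s)
    r_pos = ranks[t == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(
    records: pd.DataFrame,
    average: str = "micro",
    per_country: bool = False,
) -> MetricsReport:
    """Full scalar report; AUC is None when the truth set has one class."""
    report = classification_metrics(confusion(records), average=average)
    try:
        report.auc = auc(records)
    except UndefinedMetricError:
        report.auc = None
    for col, attr in (("fit_s", "mean_fit_s"), ("predict_s", "mean_predict_s")):
        if col in records.columns:
            setattr(report, attr, float(records[col].mean()))
    if per_country:
        report.per_country = per_country_report(records, average=average)
    return report


def per_country_report(
    records: pd.DataFrame, average: str = "micro"
) -> dict[str, MetricsReport]:
    """Metrics per country; single-truth-class countries get AUC = None."""
    out: dict[str, MetricsReport] = {}
    for country, group in records.groupby("country", sort=True):
        out[str(country)] = evaluate(group, average=average)
    return out
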