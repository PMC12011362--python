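"""Example-based multi-label metrics and per-class sensitivity/specificity.

For true label sets L_i and predicted sets L*_i over an M-label space:

* precision     = mean |L∩L*| / |L*|
* coverage      = mean |L∩L*| / |L|   (example-based recall)
* accuracy      = mean |L∩L*| / |L∪L*|  (Jaccard)
* absolute true = fraction of samples with L = L* exactly
* absolute false= mean (|L∪L*| − |L∩L*|) / M  (normalized Hamming-type error)

An empty predicted set against a non-empty truth makes the precision
summand 0/0; it is defined as 0, penalizing the empty prediction.  The
analogous conventions apply to coverage and accuracy.  When truth and
prediction are both empty the sample is an exact match and the
precision/coverage/accuracy summands are 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqdata import LabelSpace


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    coverage: float
    accuracy: float
    absolute_true: float
    absolute_false: float
    N: int
    M: int

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "coverage": self.coverage,
            "accuracy": self.accuracy,
            "absolute_true": self.absolute_true,
            "absolute_false": self.absolute_false,
        }


@dataclass(frozen=True)
class ClassMetrics:
    label: str
    TP: int
    TN: int
    FP: int
    FN: int
    sensitivity: float  # NaN when the label has no positive samples
    specificity: float  # NaN when the label has no negative samples


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def multilabel_metrics(true_labels, predicted_labels, M: int) -> MetricsReport:
    """The five example-based metrics over parallel lists of label sets."""
    true_labels = [frozenset(s) for s in true_labels]
    predicted_labels = [frozenset(s) for s in predicted_labels]
    n = len(true_labels)
    if n == 0:
        raise MetricsError("need at least one sample")
    if len(predicted_labels) != n:
        raise MetricsError("truth and prediction lists differ in length")
    for s in true_labels + predicted_labels:
        if len(s) > M:
            raise MetricsError("label set larger than the label space")
    prec = cov = acc = atrue = afalse = 0.0
    for t, p in zip(true_labels, predicted_labels):
        inter = len(t & p)
        union = len(t | p)
        if union == 0:  # both empty: exact match
            prec += 1.0
            cov += 1.0
            acc += 1.0
        else:
            prec += _ratio(inter, len(p))
            cov += _ratio(inter, len(t))
            acc += _ratio(inter, union)
        atrue += 1.0 if t == p else 0.0
        afalse += (union - inter) / M
    return MetricsReport(
        precision=prec / n, coverage=cov / n, accuracy=acc / n,
        absolute_true=atrue / n, absolute_false=afalse / n, N=n, M=M,
    )


def per_class_metrics(true_labels, predicted_labels,
                      label_space: LabelSpace) -> list[ClassMetrics]:
    """One-vs-rest confusion counts and sensitivity/specificity per label.

    A label with no positive samples has undefined sensitivity, reported
    as NaN with a warning (never silently 0); likewise for specificity
    with no negatives.
    """
    true_labels = [frozenset(s) for s in true_labels]
    predicted_labels = [frozenset(s) for s in predicted_labels]
    if len(true_labels) != len(predicted_labels):
        raise MetricsError("truth and prediction lists differ in length")
    space = set(label_space.names)
    for s in true_labels + predicted_labels:
        if not s <= space:
            raise MetricsError(f"labels outside the label space: {sorted(s - space)}")
    out = []
    for name in label_space.names:
        tp = fn = fp = tn = 0
        for t, p in zip(true_labels, predicted_labels):
            truth, pred = name in t, name in p
            if truth and pred:
                tp += 1
            elif truth:
                fn += 1
            elif pred:
                fp += 1
            else:
                tn += 1
        if tp + fn == 0:
            warnings.warn(f"label {name!r} has no positive samples; "
                          "sensitivity undefined", stacklevel=2)
            sens = float("nan")
        else:
            sens = tp / (tp + fn)
        if tn + fp == 0:
            warnings.warn(f"label {name!r} has no negative samples; "
                          "specificity undefined", stacklevel=2)
            spec = float("nan")
        else:
            spec = tn / (tn + fp)
        out.append(ClassMetrics(name, tp, tn, fp, fn, sens, spec))
    return out


def metrics_table(report: MetricsReport) -> pd.DataFrame:
    return pd.DataFrame([report.as_dict()])


def class_metrics_table(rows: list[ClassMetrics]) -> pd.DataFrame:
    return pd.DataFrame([
        {"label": r.label, "TP": r.TP, "TN": r.TN, "FP": r.FP, "FN": r.FN,
         "sensitivity": r.sensitivity, "specificity": r.specificity}
        for r in rows
    ])
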