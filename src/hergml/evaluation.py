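"""Binary-classification metrics for binder/non-binder models.

The binder class is the positive class throughout.  Metrics follow the
standard confusion-matrix definitions: Matthews correlation coefficient
(MCC), accuracy (ACC), precision, sensitivity (SE, recall on binders) and
specificity (SP, recall on non-binders), plus the area under the ROC curve
computed as the rank statistic P(score(binder) > score(non-binder)) with
ties counted 1/2.

Zero-denominator conventions (flagged in the report): MCC -> 0.0,
precision/SE/SP -> 0.0.  These never occur on non-degenerate inputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

BINDER = "binder"
NON_BINDER = "non-binder"


@dataclass
class EvaluationReport:
    """Confusion counts and derived metrics for one model evaluation."""

    TP: int
    TN: int
    FP: int
    FN: int
    MCC: float
    ACC: float
    precision: float
    SE: float
    SP: float
    AUC: float | None = None
    n: int = 0
    degenerate: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _as_binary(labels: Sequence) -> np.ndarray:
    """Map labels to {0,1} with binder=1. Accepts strings or 0/1 ints."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "ifb":
        return arr.astype(int)
    return (arr == BINDER).astype(int)


def confusion_counts(truth: Sequence, predicted: Sequence) -> tuple[int, int, int, int]:
    """Count (TP, TN, FP, FN) with the binder class as positive.

    Raises ``ValueError`` on length mismatch.  Empty inputs give all zeros.
    """
    t = _as_binary(truth)
    p = _as_binary(predicted)
    if t.shape != p.shape:
        raise ValueError(
            f"truth ({t.shape[0]}) and prediction ({p.shape[0]}) lengths differ"
        )
    tp = int(np.sum((t == 1) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    return tp, tn, fp, fn


def metrics(tp: int, tn: int, fp: int, fn: int) -> EvaluationReport:
    """Compute MCC, ACC, precision, SE and SP from confusion counts.

    MCC = (TN*TP - FN*FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN));
    ACC = (TP+TN)/n; precision = TP/(TP+FP); SE = TP/(TP+FN);
    SP = TN/(TN+FP).
    """
    for name, v in (("TP", tp), ("TN", tn), ("FP", fp), ("FN", fn)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("all confusion counts are zero")

    degenerate: list[str] = []

    acc = (tp + tn) / n

    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if mcc_den == 0:
        mcc = 0.0
        degenerate.append("MCC")
    else:
        mcc = (tn * tp - fn * fp) / mcc_den

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    se = _ratio(tp, tp + fn, "SE")
    sp = _ratio(tn, tn + fp, "SP")

    return EvaluationReport(
        TP=tp, TN=tn, FP=fp, FN=fn,
        MCC=mcc, ACC=acc, precision=precision, SE=se, SP=sp,
        n=n, degenerate=degenerate,
    )


def evaluate(truth: Sequence, predicted: Sequence,
             probabilities: Sequence[float] | None = None) -> EvaluationReport:
    """Full report from label vectors, optionally with ROC AUC."""
    tp, tn, fp, fn = confusion_counts(truth, predicted)
    report = metrics(tp, tn, fp, fn)
    if probabilities is not None:
        report.AUC = auc(truth, probabilities)
    return report


def auc(truth: Sequence, scores: Sequence[float]) -> float:
    """ROC AUC as the Mann-Whitney rank statistic.

    Equals the probability that a randomly drawn binder receives a higher
    score than a randomly drawn non-binder, ties counted 0.5.  Requires
    both classes present.
    """
    t = _as_binary(truth)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("truth and score lengths differ")
    n_pos = int(t.sum())
    n_neg = int(t.shape[0] - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)
    # sum of positive-class ranks, Mann-Whitney U
    u = ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def comparison_table(reports: dict[str, EvaluationReport]):
    """Side-by-side metric table, one column per model (rows = metrics)."""
    import pandas as pd

    rows = ["MCC", "ACC", "AUC", "precision", "SE", "SP"]
    data = {
        name: [getattr(rep, r) for r in rows] for name, rep in reports.items()
    }
    return pd.DataFrame(data, index=rows)
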