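"""Binary classification metrics for TFBS prediction.

Sensitivity, specificity, accuracy and Matthews correlation coefficient are
computed literally from the confusion table:

    Sen = TP/(TP+FN)        Spe = TN/(TN+FP)
    Acc = (TP+TN)/(TP+FP+TN+FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

AUC is the Mann-Whitney statistic P(score_pos > score_neg) + 0.5 P(tie),
computed from tie-adjusted ranks.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

METRIC_COLUMNS = ("Sen (%)", "Spe (%)", "Acc (%)", "MCC", "AUC")

DEFAULT_THRESHOLD = 0.5


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """The five scores plus the threshold and sample count they came from.

    ``sen``/``spe`` are NaN (reported missing, not coerced to 0) when their
    denominator is zero; a zero MCC denominator yields MCC = 0 by the
    standard convention.
    """

    sen: float
    spe: float
    acc: float
    mcc: float
    auc: float
    threshold: float
    n: int
    counts: ConfusionCounts | None = None

    def as_row(self) -> dict[str, float]:
        """Values in the tabular report layout (Sen/Spe/Acc as percentages)."""
        return {
            "Sen (%)": round(self.sen * 100, 2) if not math.isnan(self.sen) else float("nan"),
            "Spe (%)": round(self.spe * 100, 2) if not math.isnan(self.spe) else float("nan"),
            "Acc (%)": round(self.acc * 100, 2),
            "MCC": round(self.mcc, 3),
            "AUC": round(self.auc, 3),
        }


def confusion(scores, labels, threshold: float = DEFAULT_THRESHOLD) -> ConfusionCounts:
    """Threshold scores into predictions (score >= threshold -> positive)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError(f"scores shape {s.shape} != labels shape {y.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int((pred & pos).sum()),
        TN=int((~pred & ~pos).sum()),
        FP=int((pred & ~pos).sum()),
        FN=int((~pred & pos).sum()),
    )


def sen_spe_acc_mcc(c: ConfusionCounts) -> tuple[float, float, float, float]:
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    total = c.total
    if total == 0:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / total
    denom = math.sqrt((tp + fp) * (tn + fn) * (tp + fn) * (tn + fp))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return sen, spe, acc, mcc


def auc(scores, labels) -> float:
    """Rank-based AUC with ties counted half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined with a single class")
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    rank_sum_pos = ranks[y == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(scores, labels, threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    """Full report: thresholded confusion metrics plus threshold-free AUC."""
    c = confusion(scores, labels, threshold)
    sen, spe, acc, mcc = sen_spe_acc_mcc(c)
    return MetricsReport(sen=sen, spe=spe, acc=acc, mcc=mcc,
                         auc=auc(scores, labels), threshold=threshold,
                         n=c.total, counts=c)


def write_report_tsv(rows: list[tuple[dict[str, str], MetricsReport]],
                     path: str | Path) -> None:
    """Write reports as TSV; ``rows`` pairs key columns (e.g. Model) with reports."""
    if not rows:
        raise ValueError("no rows to write")
    key_cols = list(rows[0][0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(key_cols + list(METRIC_COLUMNS)) + "\n")
        for keys, report in rows:
            vals = report.as_row()
            fh.write("\t".join([str(keys[k]) for k in key_cols]
                               + [f"{vals[c]:.4g}" if not math.isnan(vals[c]) else "NA"
                                  for c in METRIC_COLUMNS]) + "\n")
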