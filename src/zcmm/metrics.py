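"""Confusion-matrix metrics and ROC/AUC.

Sensitivity, specificity, accuracy and the Matthews correlation
coefficient are computed in the miss-rate parameterization common in
nucleosome-prediction work:

    Sn  = 1 - FN/N+          Sp  = 1 - FP/N-
    Acc = 1 - (FN + FP)/(N+ + N-)
    MCC = [1 - (FN/N+ + FP/N-)]
          / sqrt[(1 + (FP - FN)/N+) (1 + (FN - FP)/N-)]

which is algebraically identical to the textbook TP/TN/FP/FN form
(property-tested against it).  AUC is the tie-corrected Mann-Whitney
probability P(score+ > score-) + 0.5 P(tie).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts: ``fn`` positives predicted negative,
    ``fp`` negatives predicted positive, out of ``n_pos``/``n_neg``."""

    n_pos: int
    n_neg: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise MetricsError("both classes must be non-empty")
        if not (0 <= self.fn <= self.n_pos):
            raise MetricsError(f"fn={self.fn} out of range [0, {self.n_pos}]")
        if not (0 <= self.fp <= self.n_neg):
            raise MetricsError(f"fp={self.fp} out of range [0, {self.n_neg}]")

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        return cls(
            n_pos=int((yt == 1).sum()),
            n_neg=int((yt == -1).sum()),
            fn=int(((yt == 1) & (yp == -1)).sum()),
            fp=int(((yt == -1) & (yp == 1)).sum()),
        )


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        d = {"sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def compute_metrics(counts: ConfusionCounts, auc: Optional[float] = None) -> MetricsReport:
    """Sn/Sp/Acc/MCC from confusion counts.

    A zero MCC denominator (the classifier predicts one class only)
    yields MCC = 0 with a warning, the common convention.
    """
    np_, nn, fn, fp = counts.n_pos, counts.n_neg, counts.fn, counts.fp
    sn = 1.0 - fn / np_
    sp = 1.0 - fp / nn
    acc = 1.0 - (fn + fp) / (np_ + nn)
    num = 1.0 - (fn / np_ + fp / nn)
    den_sq = (1.0 + (fp - fn) / np_) * (1.0 + (fn - fp) / nn)
    if den_sq <= 0:
        warnings.warn(
            "MCC denominator is zero (degenerate predictions); reporting MCC=0",
            RuntimeWarning,
            stacklevel=2,
        )
        mcc = 0.0
    else:
        mcc = num / np.sqrt(den_sq)
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=float(mcc), auc=auc)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, np.ndarray]:
    """AUC and ROC points for continuous scores against +1/-1 labels.

    Returns ``(auc, points)`` where ``points`` is an array of
    (fpr, tpr, threshold) rows sorted by decreasing threshold.  The AUC
    equals the tie-corrected pairwise Mann-Whitney statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise MetricsError("scores and labels must be 1-D and aligned")
    if not ((y == 1).any() and (y == -1).any()):
        raise MetricsError("both classes must be present for ROC analysis")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, np.column_stack([fpr, tpr, thr])


def report_to_json(
    reports: Sequence[MetricsReport],
    mean: MetricsReport,
    path: Union[str, Path],
    config: Optional[dict] = None,
) -> None:
    doc = {
        "per_fold": [r.to_dict() for r in reports],
        "mean": mean.to_dict(),
    }
    if config is not None:
        doc["config"] = config
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def report_to_tsv(
    reports: Sequence[MetricsReport], mean: MetricsReport, path: Union[str, Path]
) -> None:
    cols = ["fold", "sn", "sp", "acc", "mcc", "auc"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, r in enumerate(reports, 1):
            fh.write(
                f"{i}\t{r.sn:.6f}\t{r.sp:.6f}\t{r.acc:.6f}\t{r.mcc:.6f}\t"
                + (f"{r.auc:.6f}" if r.auc is not None else "NA")
                + "\n"
            )
        fh.write(
            f"mean\t{mean.sn:.6f}\t{mean.sp:.6f}\t{mean.acc:.6f}\t{mean.mcc:.6f}\t"
            + (f"{mean.auc:.6f}" if mean.auc is not None else "NA")
            + "\n"
        )


def roc_points_to_tsv(points: np.ndarray, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\tthreshold\n")
        for fpr, tpr, thr in points:
            fh.write(f"{fpr!r}\t{tpr!r}\t{thr!r}\n")
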