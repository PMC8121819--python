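"""Pixelwise sensitivity/specificity (ROC) validation against ground truth.

Automated masks are compared pixel-for-pixel with binary ground-truth
masks (manual delineation, or the synthetic generator's exact truth).
Per image and per channel this yields a confusion table and one ROC
operating point (false positive rate, sensitivity); channel-wise means
summarise a validation set. No boundary tolerance is applied — raw
pixels are compared.

The false positive rate is implemented as FP/(FP+TN), so the identity
FPR = 1 − specificity holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import BinaryMask


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion table of a predicted vs truth mask pair."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RocPoint:
    """One ROC operating point for one image and channel.

    ``None`` values flag undefined rates (empty truth foreground or
    background).
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    fpr: Optional[float]
    channel: str
    source_id: str = ""


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Count TP/FP/TN/FN pixels between prediction and ground truth."""
    p, t = pred.values, truth.values
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def sensitivity(c: ConfusionCounts) -> Optional[float]:
    """True positive rate TP/(TP+FN); NA when the truth mask is empty."""
    denom = c.tp + c.fn
    return c.tp / denom if denom > 0 else None


def specificity(c: ConfusionCounts) -> Optional[float]:
    """True negative rate TN/(TN+FP); NA when the truth background is empty."""
    denom = c.tn + c.fp
    return c.tn / denom if denom > 0 else None


def false_positive_rate(c: ConfusionCounts) -> Optional[float]:
    """FP/(FP+TN), evaluated as 1 − specificity so the identity is exact
    in floating point as well as algebraically; NA when undefined."""
    s = specificity(c)
    return 1.0 - s if s is not None else None


def roc_point(pred: BinaryMask, truth: BinaryMask, channel: str, source_id: str = "") -> RocPoint:
    """Confusion → one ROC operating point for a channel of one image."""
    c = confusion(pred, truth)
    return RocPoint(
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        fpr=false_positive_rate(c),
        channel=channel,
        source_id=source_id,
    )


def roc_table(
    pairs: Sequence[tuple[BinaryMask, BinaryMask, BinaryMask, BinaryMask, str]],
) -> tuple[list[RocPoint], dict[str, dict[str, Optional[float]]]]:
    """ROC points for a set of (pred green, pred red, truth green, truth red, id).

    Returns one point per image per channel plus channel-wise mean
    sensitivity/specificity, averaging only over images where the rate
    is defined (NA-aware).
    """
    if not pairs:
        raise ValueError("at least one prediction/truth pair is required")
    points: list[RocPoint] = []
    for pred_g, pred_r, truth_g, truth_r, source_id in pairs:
        points.append(roc_point(pred_g, truth_g, "green", source_id))
        points.append(roc_point(pred_r, truth_r, "red", source_id))
    means: dict[str, dict[str, Optional[float]]] = {}
    for channel in ("green", "red"):
        ch_points = [p for p in points if p.channel == channel]
        means[channel] = {}
        for attr in ("sensitivity", "specificity", "fpr"):
            vals = [getattr(p, attr) for p in ch_points if getattr(p, attr) is not None]
            means[channel][attr] = float(np.mean(vals)) if vals else None
    return points, means


def roc_points_frame(points: Sequence[RocPoint]) -> pd.DataFrame:
    """Tabulate ROC points for CSV export."""
    return pd.DataFrame(
        [
            {
                "source_id": p.source_id,
                "channel": p.channel,
                "sensitivity": p.sensitivity,
                "specificity": p.specificity,
                "fpr": p.fpr,
            }
            for p in points
        ]
    )
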