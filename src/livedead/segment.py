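"""Joint Otsu thresholding and binarization of the two stain channels.

A single global threshold is computed from the pooled histogram of the
preprocessed green and red channels (not per-channel Otsu): pixels of
both channels enter one histogram, and the threshold maximizing the
between-class variance is shared by both binarizations. The combined
(green OR red) mask gives total bacterial area; the red mask alone gives
dead area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import BinaryMask, MicrographFrame
from .preprocess import PreprocessParams, preprocess_frame

logger = logging.getLogger(__name__)


class NoThresholdError(ValueError):
    """Raised when the pooled image is constant and no threshold exists."""


@dataclass
class SegmentationResult:
    """Masks and threshold produced by segmenting one frame.

    Invariant: ``combined_mask`` is the pixelwise OR of ``green_mask``
    and ``red_mask``; the threshold is ``None`` only for blank frames
    that could not be thresholded (all masks empty).
    """

    green_mask: BinaryMask
    red_mask: BinaryMask
    combined_mask: BinaryMask
    threshold: Optional[float]


def joint_otsu_threshold(
    green: np.ndarray,
    red: np.ndarray,
    n_bins: int = 256,
    max_val: Optional[int] = None,
) -> int:
    """Otsu threshold of the pooled green+red pixel histogram.

    All pixels of both channels are pooled into one ``n_bins`` histogram
    over ``[0, max_val]`` and the threshold maximizing the between-class
    variance is returned, as the largest intensity of the highest
    background bin (so foreground is ``intensity > t``). Ties are broken
    toward the lowest qualifying threshold.

    Raises
    ------
    NoThresholdError
        If the pooled pixels take a single distinct value.
    """
    green = np.asarray(green)
    red = np.asarray(red)
    if green.shape != red.shape:
        raise ValueError(f"channel shapes differ: {green.shape} vs {red.shape}")
    if max_val is None:
        if green.dtype == np.uint8:
            max_val = 255
        elif green.dtype == np.uint16:
            max_val = 65535
        else:
            max_val = int(max(green.max(), red.max()))
    pooled = np.concatenate([green.ravel(), red.ravel()])
    if pooled.min() == pooled.max():
        raise NoThresholdError(
            "pooled image is constant; no threshold exists"
        )
    hist, edges = np.histogram(pooled, bins=n_bins, range=(0, max_val + 1))
    hist = hist.astype(np.float64)
    total = hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(hist)                      # mass of class 0 for split after bin k
    m0 = np.cumsum(hist * centers)            # unnormalised first moment of class 0
    w1 = total - w0
    m1 = m0[-1] - m0
    valid = (w0 > 0) & (w1 > 0)
    between = np.zeros(n_bins)
    between[valid] = (
        w0[valid] * w1[valid]
        * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    )
    k = int(np.argmax(between[:-1]))  # last bin cannot split; argmax takes lowest tie
    # Largest representable intensity inside bin k.
    t = int(np.ceil(edges[k + 1]) - 1)
    return t


def binarize(channel: np.ndarray, t: float, role: str = "combined") -> BinaryMask:
    """Mask of pixels with intensity strictly greater than ``t``."""
    return BinaryMask(values=np.asarray(channel) > t, role=role)


def combine_masks(green_mask: BinaryMask, red_mask: BinaryMask) -> BinaryMask:
    """Pixelwise OR of the two channel masks (total bacterial area)."""
    if green_mask.shape != red_mask.shape:
        raise ValueError(
            f"mask shapes differ: {green_mask.shape} vs {red_mask.shape}"
        )
    return BinaryMask(values=green_mask.values | red_mask.values, role="combined")


def segment_frame(frame: MicrographFrame, params: Optional[PreprocessParams] = None) -> SegmentationResult:
    """Preprocess and segment one frame with a shared joint-Otsu threshold.

    Blank frames (constant after preprocessing) yield an empty
    segmentation — all-false masks and ``threshold=None`` — with a
    warning, rather than aborting a batch.
    """
    if params is None:
        params = PreprocessParams()
    pre = preprocess_frame(frame, params)
    try:
        t = joint_otsu_threshold(pre.green, pre.red, max_val=frame.max_val)
    except NoThresholdError:
        warnings.warn(
            f"{frame.source_id or 'frame'}: blank frame, no threshold exists; "
            "returning empty segmentation",
            stacklevel=2,
        )
        empty = np.zeros(frame.shape, dtype=bool)
        return SegmentationResult(
            green_mask=BinaryMask(empty, "green"),
            red_mask=BinaryMask(empty.copy(), "red"),
            combined_mask=BinaryMask(empty.copy(), "combined"),
            threshold=None,
        )
    green_mask = binarize(pre.green, t, role="green")
    red_mask = binarize(pre.red, t, role="red")
    return SegmentationResult(
        green_mask=green_mask,
        red_mask=red_mask,
        combined_mask=combine_masks(green_mask, red_mask),
        threshold=float(t),
    )
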