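"""Pixel counts to viability and coverage, per frame, per slice, per batch.

Viability here is *area-based*: the red (dead-stain) foreground area is
subtracted from the combined (green OR red) foreground area and the
remainder expressed as a percentage of the combined area. This assumes
that, within a single-species biofilm, stained area is proportional to
cell number; for multi-species biofilms the number is better read as
"percentage of live cell area" than as viability. Coverage — combined
foreground as a percentage of all image pixels — serves as a biomass
proxy.

Frames in which no bacteria are detected report viability as undefined
(NA), never as 0 or 100, so treated blank fields stay distinguishable
from genuinely all-dead fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import ZStack
from .preprocess import PreprocessParams
from .segment import SegmentationResult, segment_frame


@dataclass
class ViabilityRecord:
    """Per-frame (or per-slice) quantification result.

    Invariants: ``live_px + dead_px == total_px``;
    ``pct_alive = 100 * live_px / total_px`` when ``total_px > 0`` and
    ``None`` (NA) otherwise; ``pct_coverage = 100 * total_px / n_px``.
    """

    source_id: str
    total_px: int
    dead_px: int
    live_px: int
    pct_alive: Optional[float]
    pct_coverage: float
    threshold: Optional[float] = None
    z_index: Optional[int] = None
    depth_um: Optional[float] = None


@dataclass
class BatchSummary:
    """Dispersion summary of a batch of viability records.

    ``cv_pct`` is the coefficient of variation, 100·sd/mean, of the
    defined ``pct_alive`` values; undefined when the mean is zero or
    fewer than two records are defined.
    """

    n: int
    n_undefined: int
    mean_pct_alive: float
    sd_pct_alive: Optional[float]
    cv_pct: Optional[float]
    mean_pct_coverage: float
    sd_pct_coverage: Optional[float]


def quantify_frame(
    seg: SegmentationResult,
    source_id: str = "",
    z_index: Optional[int] = None,
    depth_um: Optional[float] = None,
) -> ViabilityRecord:
    """Turn a segmentation into pixel counts and percentages.

    dead = red foreground, total = combined foreground,
    live = total − dead; % alive = 100·live/total (NA if total is 0);
    % coverage = 100·total/(image pixels).
    """
    dead_px = seg.red_mask.count
    total_px = seg.combined_mask.count
    live_px = total_px - dead_px
    n_px = seg.combined_mask.values.size
    pct_alive = 100.0 * live_px / total_px if total_px > 0 else None
    pct_coverage = 100.0 * total_px / n_px
    return ViabilityRecord(
        source_id=source_id,
        total_px=total_px,
        dead_px=dead_px,
        live_px=live_px,
        pct_alive=pct_alive,
        pct_coverage=pct_coverage,
        threshold=seg.threshold,
        z_index=z_index,
        depth_um=depth_um,
    )


def quantify_stack(
    stack: ZStack,
    params: Optional[PreprocessParams] = None,
    z_step: Optional[float] = None,
) -> list[ViabilityRecord]:
    """Segment and quantify every slice of a z-stack independently.

    Each slice is processed with the same parameters; ``depth_um`` is
    measured from the first slice as ``z_index * z_step`` (z_step
    defaults to the stack's own, typically 1 µm).
    """
    if z_step is None:
        z_step = stack.z_step
    records = []
    for z, frame in enumerate(stack.frames):
        seg = segment_frame(frame, params)
        records.append(
            quantify_frame(
                seg,
                source_id=frame.source_id,
                z_index=z,
                depth_um=z * z_step,
            )
        )
    return records


def detect_origin(records: Sequence[ViabilityRecord], coverage_floor: float = 0.5) -> int:
    """Index of the first slice whose coverage exceeds ``coverage_floor`` %.

    Mirrors imaging "from the first plane in which bacteria were
    identified"; off by default in the pipeline — callers opt in.
    """
    for rec in records:
        if rec.pct_coverage > coverage_floor:
            return rec.z_index or 0
    raise ValueError(f"no slice exceeds {coverage_floor}% coverage")


def summarize_batch(records: Sequence[ViabilityRecord]) -> BatchSummary:
    """Mean, sample SD (n−1) and CV of viability over a batch.

    Records with undefined ``pct_alive`` are excluded and counted in
    ``n_undefined``. With a single defined record the SD (and CV) is NA.
    """
    alive = [r.pct_alive for r in records if r.pct_alive is not None]
    coverage = [r.pct_coverage for r in records if r.pct_alive is not None]
    n_undefined = len(records) - len(alive)
    if not alive:
        raise ValueError("no record has a defined pct_alive")
    mean = float(np.mean(alive))
    mean_cov = float(np.mean(coverage))
    if len(alive) >= 2:
        sd = float(np.std(alive, ddof=1))
        sd_cov = float(np.std(coverage, ddof=1))
        cv = 100.0 * sd / mean if mean != 0 else None
    else:
        sd = sd_cov = cv = None
    return BatchSummary(
        n=len(alive),
        n_undefined=n_undefined,
        mean_pct_alive=mean,
        sd_pct_alive=sd,
        cv_pct=cv,
        mean_pct_coverage=mean_cov,
        sd_pct_coverage=sd_cov,
    )
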