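"""Reading and writing micrographs, masks and result tables.

The on-disk world of confocal exports is messy: channels may be stored as
interleaved samples (RGB-style), as separate pages, or a z-stack may carry
two samples per pixel. Everything is normalised here into two containers:

* :class:`MicrographFrame` — one two-channel (green/red) 2D image,
* :class:`ZStack` — an ordered list of frames at a fixed physical z step.

Intensities are never rescaled on read; the pipeline operates on raw
integer counts at the image's native bit depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Roles a binary mask can play in the pipeline.
MASK_ROLES = ("green", "red", "combined", "truth_live", "truth_dead", "truth_any")

_INT_DTYPES = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


@dataclass(frozen=True)
class BinaryMask:
    """2D boolean field marking pixels classified as bacteria.

    Parameters
    ----------
    values
        Boolean array, same shape as the parent frame.
    role
        One of :data:`MASK_ROLES` — which channel (or truth layer) the
        mask describes.
    """

    values: np.ndarray
    role: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=bool)
        if values.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {values.shape}")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")
        object.__setattr__(self, "values", values)

    @property
    def count(self) -> int:
        """Number of foreground (True) pixels."""
        return int(np.count_nonzero(self.values))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class MicrographFrame:
    """One two-channel fluorescence micrograph.

    ``green`` holds the SYTO 9 (total/live stain) channel and ``red`` the
    propidium iodide (dead stain) channel, both as non-negative integer
    arrays of identical shape.
    """

    green: np.ndarray
    red: np.ndarray
    bit_depth: int = 8
    pixel_size: Optional[float] = None  #: µm per pixel, if known
    source_id: str = ""

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.green.shape != self.red.shape:
            raise ValueError(
                f"channel shapes differ: green {self.green.shape} vs red {self.red.shape}"
            )
        if self.green.ndim != 2 or min(self.green.shape) < 2:
            raise ValueError(f"channels must be 2D and at least 2x2, got {self.green.shape}")
        hi = self.max_val
        for name, ch in (("green", self.green), ("red", self.red)):
            if not np.issubdtype(ch.dtype, np.integer):
                raise TypeError(f"{name} channel must be an integer array, got {ch.dtype}")
            if ch.min() < 0 or ch.max() > hi:
                raise ValueError(f"{name} intensities outside [0, {hi}]")

    @property
    def max_val(self) -> int:
        """Largest representable intensity, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape


@dataclass
class ZStack:
    """Ordered confocal z-series of :class:`MicrographFrame` objects."""

    frames: list[MicrographFrame]
    z_step: float = 1.0  #: physical slice increment in µm
    origin: int = 0  #: index of the first plane containing bacteria

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a ZStack needs at least one frame")
        if self.z_step <= 0:
            raise ValueError(f"z_step must be positive, got {self.z_step}")
        shape = self.frames[0].shape
        depth = self.frames[0].bit_depth
        for i, fr in enumerate(self.frames):
            if fr.shape != shape or fr.bit_depth != depth:
                raise ValueError(f"frame {i} differs in shape or bit depth from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def _validate_channel_map(channel_map: dict[str, int]) -> tuple[int, int]:
    try:
        g, r = int(channel_map["green"]), int(channel_map["red"])
    except KeyError as exc:
        raise ValueError("channel_map must provide both 'green' and 'red' indices") from exc
    if g == r:
        raise ValueError(f"channel_map indices must be distinct, got green={g} red={r}")
    if g < 0 or r < 0:
        raise ValueError("channel indices must be non-negative")
    return g, r


def _bit_depth_of(arr: np.ndarray) -> int:
    try:
        return _INT_DTYPES[arr.dtype]
    except KeyError:
        raise ValueError(f"unsupported pixel dtype {arr.dtype}; expected uint8 or uint16")


def read_micrograph(
    path,
    channel_map: dict[str, int],
    *,
    pixel_size: Optional[float] = None,
    z_step: float = 1.0,
):
    """Read a TIFF micrograph or z-stack, resolving channel roles.

    Channel layout detection, in order:

    1. a trailing *samples* axis (length ≤ 4, e.g. RGB-interleaved) holds
       the channels; any leading axis is z;
    2. a 4D page/channel layout (pages × channels × y × x) — the second
       axis holds the channels;
    3. otherwise a 3D array is treated as page-per-channel: the leading
       page axis holds the channels of a single frame.

    ``channel_map`` maps the roles ``green`` and ``red`` to indices along
    whichever axis holds the channels; unmapped channels (e.g. an unused
    blue sample) are ignored. Intensities are returned untouched.

    Returns
    -------
    MicrographFrame or ZStack
        A frame for single-plane inputs, a stack for multi-page inputs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    g_idx, r_idx = _validate_channel_map(channel_map)

    arr = tifffile.imread(path)
    arr = np.asarray(arr)

    if arr.ndim == 2:
        raise ValueError(f"{path}: single-channel image cannot satisfy a two-channel map")

    def frame_from(stack2d: np.ndarray, axis: int, source: str) -> MicrographFrame:
        n = stack2d.shape[axis]
        if max(g_idx, r_idx) >= n:
            raise ValueError(f"{source}: channel_map requests index {max(g_idx, r_idx)} "
                             f"but only {n} channels present")
        if n > 2:
            logger.debug("%s: ignoring %d unmapped channel(s)", source, n - 2)
        green = np.take(stack2d, g_idx, axis=axis)
        red = np.take(stack2d, r_idx, axis=axis)
        return MicrographFrame(
            green=green, red=red, bit_depth=_bit_depth_of(green),
            pixel_size=pixel_size, source_id=source,
        )

    if arr.ndim == 3 and arr.shape[-1] <= 4:
        # Y x X x S interleaved samples, single plane.
        return frame_from(arr, axis=-1, source=f"{path.name}")
    if arr.ndim == 4:
        # Z x C x Y x X or Z x Y x X x S.
        ch_axis = 3 if arr.shape[-1] <= 4 else 1
        frames = [
            frame_from(arr[z], axis=ch_axis - 1, source=f"{path.name}[z={z}]")
            for z in range(arr.shape[0])
        ]
        return ZStack(frames=frames, z_step=z_step)
    if arr.ndim == 3:
        # Page-per-channel single frame.
        return frame_from(arr, axis=0, source=f"{path.name}")
    raise ValueError(f"{path}: cannot interpret array of shape {arr.shape}")


def read_mask(path, role: str = "combined") -> BinaryMask:
    """Read a binary mask image (TIFF or PNG); any pixel > 0 is foreground."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an RGB(A) export of a binary mask
        arr = arr.max(axis=-1)
    return BinaryMask(values=arr > 0, role=role)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as an 8-bit image: foreground 255, background 0."""
    path = Path(path)
    img = np.where(mask.values, 255, 0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def write_frame(frame: MicrographFrame, path) -> None:
    """Write a two-channel frame as a 2-page TIFF (page 0 green, page 1 red)."""
    tifffile.imwrite(Path(path), np.stack([frame.green, frame.red], axis=0))


def write_stack(stack: ZStack, path) -> None:
    """Write a z-stack as a Z x C x Y x X TIFF (channel 0 green, 1 red)."""
    arr = np.stack(
        [np.stack([fr.green, fr.red], axis=0) for fr in stack.frames], axis=0
    )
    tifffile.imwrite(Path(path), arr)


RESULT_COLUMNS = [
    "source_id", "z_index", "depth_um", "total_px", "dead_px",
    "live_px", "pct_alive", "pct_coverage", "threshold",
]


def results_frame(records: Sequence) -> pd.DataFrame:
    """Tabulate :class:`~livedead.quantify.ViabilityRecord` objects."""
    if not records:
        raise ValueError("no records to tabulate")
    rows = []
    for rec in records:
        rows.append({col: getattr(rec, col, None) for col in RESULT_COLUMNS})
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_table(records: Sequence, path) -> None:
    """Write per-frame viability records to CSV.

    One row per record; undefined percentages (no bacteria detected) are
    serialized as ``NA`` so blank fields stay distinguishable from
    all-dead fields.
    """
    df = results_frame(records)
    df.to_csv(Path(path), index=False, na_rep="NA", float_format="%.4f")
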