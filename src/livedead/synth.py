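"""Synthetic two-channel micrographs with exact live/dead ground truth.

The generator emulates what a confocal field of a live/dead-stained
biofilm looks like to the pipeline: cocci (disks) and rods (capsules)
placed at random positions and orientations, live cells rendered into
the green channel and dead cells into the red channel, plus the three
artifacts the preprocessing stage exists to suppress —

* a smooth red *haze* (extracellular DNA / EPS stained by propidium
  iodide), built from low-frequency random blobs;
* a multiplicative *illumination gradient* across the field;
* additive Gaussian (optionally Poisson) sensor noise.

Ground-truth masks are taken before noise and illumination are applied,
so downstream metrics measure the pipeline, not the generator. The true
(area-based) viability is defined exactly as the pipeline defines it:
100 · |live pixels| / |live ∪ dead pixels|.

Default geometry (cocci radius 4 px, rods 14 × 4 px) corresponds to a
x40-objective-like sampling where individual bacteria are resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Optional

import numpy as np
from scipy import ndimage as ndi

from .io import BinaryMask, MicrographFrame, ZStack

CELL_SHAPES = ("cocci", "rod", "mixed")

#: rejection-sampling retry budget per cell when overlap is disallowed
_MAX_TRIES_PER_CELL = 200


@dataclass
class SynthSpec:
    """Parameters of one synthetic micrograph.

    Intensities are in native 8-bit units (0–255) unless ``bit_depth``
    says otherwise. ``bleedthrough`` is the fraction of each dead cell's
    intensity leaked into the green channel (SYTO 9 also enters dead
    cells in practice; off by default so the truth stays unambiguous).
    The same spec and seed always produce bit-identical output.
    """

    width: int = 256
    height: int = 256
    n_cells: int = 60
    frac_dead: float = 0.3
    shape: str = "cocci"
    cocci_radius: int = 4
    rod_length: int = 14
    rod_width: int = 4
    cell_intensity_mean: float = 180.0
    cell_intensity_sd: float = 25.0
    bleedthrough: float = 0.0
    haze_amplitude: float = 40.0
    haze_sigma: float = 20.0
    illumination_gradient: float = 0.2
    noise_sd: float = 12.0
    poisson_noise: bool = False
    allow_overlap: bool = False
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_dead <= 1.0:
            raise ValueError(f"frac_dead must be in [0, 1], got {self.frac_dead}")
        if self.shape not in CELL_SHAPES:
            raise ValueError(f"shape must be one of {CELL_SHAPES}, got {self.shape!r}")
        for name in ("width", "height", "cocci_radius", "rod_length", "rod_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if not 0.0 <= self.bleedthrough <= 1.0:
            raise ValueError("bleedthrough must be in [0, 1]")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        return cls(**d)


@dataclass
class CellRecord:
    """One placed cell: geometry, viability label and rendered intensity."""

    center: tuple[float, float]  # (row, col)
    shape: str  # "cocci" or "rod"
    angle: float  # radians; 0 for cocci
    dead: bool
    intensity: float
    area_px: int


@dataclass
class GroundTruth:
    """Exact pre-noise truth of a generated frame."""

    live_mask: BinaryMask
    dead_mask: BinaryMask
    any_mask: BinaryMask
    true_viability_pct: Optional[float]
    cells: list[CellRecord] = field(default_factory=list)


def _cell_footprint(spec: SynthSpec, shape: str, center: tuple[float, float],
                    angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates (rows, cols) covered by one cell, clipped to the field."""
    cy, cx = center
    if shape == "cocci":
        r = spec.cocci_radius
        half = r
    else:
        half = spec.rod_length / 2.0 + spec.rod_width
    y0 = max(int(np.floor(cy - half - 1)), 0)
    y1 = min(int(np.ceil(cy + half + 1)) + 1, spec.height)
    x0 = max(int(np.floor(cx - half - 1)), 0)
    x1 = min(int(np.ceil(cx + half + 1)) + 1, spec.width)
    if y0 >= y1 or x0 >= x1:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    if shape == "cocci":
        inside = dy * dy + dx * dx <= spec.cocci_radius ** 2
    else:
        # Capsule: distance to the central segment of length (L - w) <= w/2.
        ux, uy = np.cos(angle), np.sin(angle)
        seg_half = max(spec.rod_length - spec.rod_width, 0) / 2.0
        proj = np.clip(dx * ux + dy * uy, -seg_half, seg_half)
        ddx = dx - proj * ux
        ddy = dy - proj * uy
        inside = ddx * ddx + ddy * ddy <= (spec.rod_width / 2.0) ** 2
    return yy[inside], xx[inside]


def _haze_field(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth non-negative random blobs scaled to ``haze_amplitude``."""
    raw = rng.normal(size=(spec.height, spec.width))
    smooth = ndi.gaussian_filter(raw, sigma=spec.haze_sigma)
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-12:
        return np.zeros_like(smooth)
    return spec.haze_amplitude * (smooth - lo) / (hi - lo)


def _illumination(spec: SynthSpec) -> np.ndarray:
    """Multiplicative gain falling linearly from 1 to 1−gradient across x."""
    if spec.width == 1:
        return np.ones((spec.height, spec.width))
    ramp = 1.0 - spec.illumination_gradient * (np.arange(spec.width) / (spec.width - 1))
    return np.broadcast_to(ramp, (spec.height, spec.width)).copy()


def generate_frame(spec: SynthSpec) -> tuple[MicrographFrame, GroundTruth]:
    """Render one synthetic two-channel frame and its exact ground truth.

    Cells are placed by rejection sampling when ``allow_overlap`` is
    false; exceeding the retry budget raises with a message naming the
    density limit. Dead labels are Bernoulli(``frac_dead``) draws per
    cell. Truth masks are taken pre-noise/pre-illumination.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    live = np.zeros((H, W), dtype=bool)
    dead = np.zeros((H, W), dtype=bool)
    green = np.zeros((H, W), dtype=np.float64)
    red = np.zeros((H, W), dtype=np.float64)
    occupied = np.zeros((H, W), dtype=bool)
    cells: list[CellRecord] = []

    for _ in range(spec.n_cells):
        shape = spec.shape
        if shape == "mixed":
            shape = "cocci" if rng.random() < 0.5 else "rod"
        is_dead = bool(rng.random() < spec.frac_dead)
        intensity = float(max(rng.normal(spec.cell_intensity_mean, spec.cell_intensity_sd), 1.0))
        placed = False
        for _try in range(_MAX_TRIES_PER_CELL):
            cy = rng.uniform(0, H - 1)
            cx = rng.uniform(0, W - 1)
            angle = float(rng.uniform(0, np.pi)) if shape == "rod" else 0.0
            rows, cols = _cell_footprint(spec, shape, (cy, cx), angle)
            if rows.size == 0:
                continue
            if not spec.allow_overlap and occupied[rows, cols].any():
                continue
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place cell {len(cells) + 1}/{spec.n_cells} after "
                f"{_MAX_TRIES_PER_CELL} tries: the requested density exceeds "
                f"what a {W}x{H} field can hold without overlap"
            )
        occupied[rows, cols] = True
        if is_dead:
            dead[rows, cols] = True
            red[rows, cols] = np.maximum(red[rows, cols], intensity)
            if spec.bleedthrough > 0:
                green[rows, cols] = np.maximum(
                    green[rows, cols], spec.bleedthrough * intensity
                )
        else:
            live[rows, cols] = True
            green[rows, cols] = np.maximum(green[rows, cols], intensity)
        cells.append(
            CellRecord(
                center=(float(cy), float(cx)),
                shape=shape,
                angle=angle,
                dead=is_dead,
                intensity=intensity,
                area_px=int(rows.size),
            )
        )

    any_mask = live | dead
    n_any = int(any_mask.sum())
    true_viability = 100.0 * live.sum() / n_any if n_any > 0 else None
    truth = GroundTruth(
        live_mask=BinaryMask(live, "truth_live"),
        dead_mask=BinaryMask(dead, "truth_dead"),
        any_mask=BinaryMask(any_mask, "truth_any"),
        true_viability_pct=true_viability,
        cells=cells,
    )

    # Imaging artifacts, applied after the truth is fixed.
    red = red + _haze_field(spec, rng)
    gain = _illumination(spec)
    green *= gain
    red *= gain
    if spec.poisson_noise:
        green = rng.poisson(np.clip(green, 0, None)).astype(np.float64)
        red = rng.poisson(np.clip(red, 0, None)).astype(np.float64)
    if spec.noise_sd > 0:
        green = green + rng.normal(0, spec.noise_sd, size=(H, W))
        red = red + rng.normal(0, spec.noise_sd, size=(H, W))

    max_val = (1 << spec.bit_depth) - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    green_i = np.clip(np.rint(green), 0, max_val).astype(dtype)
    red_i = np.clip(np.rint(red), 0, max_val).astype(dtype)
    frame = MicrographFrame(
        green=green_i,
        red=red_i,
        bit_depth=spec.bit_depth,
        source_id=f"synthetic(seed={spec.seed})",
    )
    return frame, truth


def rasterize_cells(spec: SynthSpec, cells: list[CellRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Re-render live/dead truth masks from per-cell records alone.

    Independent of :func:`generate_frame`'s internal state; used to
    check that the stored records fully determine the truth masks.
    """
    live = np.zeros((spec.height, spec.width), dtype=bool)
    dead = np.zeros((spec.height, spec.width), dtype=bool)
    for cell in cells:
        rows, cols = _cell_footprint(spec, cell.shape, cell.center, cell.angle)
        (dead if cell.dead else live)[rows, cols] = True
    return live, dead


def generate_stack(
    spec: SynthSpec,
    n_slices: int,
    viability_profile: Optional[Callable[[int], float]] = None,
    density_profile: Optional[Callable[[int], float]] = None,
) -> tuple[ZStack, list[GroundTruth]]:
    """Generate a z-stack of synthetic frames with depth-dependent structure.

    ``viability_profile(z)`` gives the live fraction at slice ``z``
    (frac_dead = 1 − profile); ``density_profile(z)`` scales ``n_cells``.
    Slice seeds are derived deterministically from ``spec.seed`` and z.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    frames, truths = [], []
    for z in range(n_slices):
        frac_dead = spec.frac_dead
        if viability_profile is not None:
            v = float(viability_profile(z))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"viability_profile({z}) = {v} outside [0, 1]")
            frac_dead = 1.0 - v
        n_cells = spec.n_cells
        if density_profile is not None:
            scale = float(density_profile(z))
            if scale < 0:
                raise ValueError(f"density_profile({z}) = {scale} is negative")
            n_cells = int(round(spec.n_cells * scale))
        # z=0 reuses spec.seed so a 1-slice stack matches generate_frame exactly
        slice_seed = (spec.seed + 7919 * z) % (1 << 31)
        slice_spec = replace(spec, frac_dead=frac_dead, n_cells=n_cells, seed=slice_seed)
        frame, truth = generate_frame(slice_spec)
        frame.source_id = f"synthetic(seed={spec.seed})[z={z}]"
        frames.append(frame)
        truths.append(truth)
    return ZStack(frames=frames, z_step=1.0), truths
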