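# Methods

## The measurement

Live/dead staining of a biofilm yields a two-channel confocal
micrograph: SYTO 9 (green) labels all bacteria with intact membranes,
propidium iodide (red) enters only membrane-compromised (dead) cells.
`livedead` turns such an image into two numbers:

* **% alive** = 100 · (total bacterial pixels − red pixels) / total
  bacterial pixels, where *total* is the union of green and red
  foreground;
* **% coverage** = 100 · total bacterial pixels / all image pixels, a
  biomass proxy.

Both are *area-based*. The underlying assumption is that, within a
single-species biofilm, stained area is proportional to cell number.
For multi-species biofilms with mixed morphologies the output is more
honestly read as "percentage of live cell area" than as viability.
There is deliberately no per-cell instance segmentation, counting or
watershed splitting: the method quantifies area, not discrete cells.

## Pipeline

1. **Channel split.** The green and red channels are separated
   according to a user-declared channel map; intensities are used at
   native bit depth (8 or 16), never rescaled.
2. **Opening by reconstruction** (both channels). A grayscale erosion
   with a disk structuring element (radius 3 px by default) forms the
   marker; geodesic dilation under the original image (8-connectivity,
   iterated to exact integer convergence) reconstructs every structure
   that survived the erosion with its exact shape; one final grayscale
   dilation with the same disk, clipped pointwise to the original,
   restores the footprint lost to the marker erosion. This removes
   specks smaller than the disk without rounding off real cells. The
   final dilation is toggleable (`apply_final_dilation`) because the
   erosion/reconstruction core alone is the idempotent filter; with
   the extra clipped dilation the operator remains anti-extensive but
   regains the eroded margin.
3. **Rolling-ball background subtraction** (red channel only).
   Propidium iodide also stains extracellular DNA, producing a smooth
   red haze that inflates the dead area. The background is the upper
   envelope of every ball (default radius 50 px) fitting under the
   intensity surface — a grayscale opening with the ball's height
   profile as structuring function. An exact opening is pinned by any
   isolated dark noise pixel, so the background is estimated on a 3×3
   mean-filtered copy and subtracted from the original (the behaviour
   of the ImageJ *Subtract Background* command, whose default
   presmoothing exists for precisely this reason). Subtraction is
   clamped at zero. The green channel gets no background subtraction:
   SYTO 9 haze is not part of the artifact model, and removing faint
   diffuse green signal would bias viability downward.
4. **Gamma adjustment** (both channels, γ = 1.5 by default). Two
   conventions are provided because "gamma 1.5" is ambiguous:
   `brighten_faint` (default) maps x → max·(x/max)^(1/γ), lifting
   faint cells toward bright ones, which is the stated purpose of the
   step; `imagej_power` maps x → max·(x/max)^γ, the literal ImageJ
   Gamma command, which for γ > 1 darkens faint pixels. Both fix 0 and
   the maximum intensity and are monotone, so they change which pixels
   clear the threshold but never reorder them.
5. **Joint Otsu threshold.** All pixels of both preprocessed channels
   are pooled into one 256-bin histogram over the full representable
   range and a single threshold t maximizing between-class variance is
   chosen (ties broken toward the lowest qualifying bin; t is reported
   as the largest intensity of the highest background bin). One shared
   threshold — not per-channel Otsu — keeps the green/red decision
   consistent: a pixel is foreground iff its intensity is *strictly
   greater* than t, in either channel.
6. **Counting.** dead = red foreground; total = green OR red
   foreground; live = total − dead. A frame with an empty combined
   mask reports % alive as NA (never 0 or 100), so a blank
   field of view is distinguishable from an all-dead one. A frame that
   is constant after preprocessing cannot be thresholded; it yields an
   empty segmentation with a warning instead of aborting a batch.

For z-stacks every slice is segmented independently with the same
parameters and reported at depth z·Δz (Δz defaults to 1 µm), measured
from the first slice. Automatic origin detection (first slice above a
0.5 % coverage floor) is available but off by default. Batch summaries
report mean, sample SD (n−1) and the coefficient of variation
100·SD/mean over records with defined viability; a single record
reports SD as NA rather than 0.

## Validation machinery

Automated masks are compared pixel-for-pixel against binary
ground-truth masks, per channel and per image:

* sensitivity = TP / (TP + FN)
* specificity = TN / (TN + FP)
* FPR = FP / (FP + TN), evaluated as 1 − specificity so the identity
  holds exactly in floating point as well as algebraically.

Rates whose denominator is zero (empty truth foreground or background)
are NA and excluded from channel means, which are taken over images,
not over pooled pixels. No boundary tolerance is applied. AUROC over
threshold sweeps is out of scope: each image contributes a single
operating point.

## Synthetic micrographs

The generator (`livedead.synth`) exists so every stage can be tested
against exact ground truth. It emulates:

* **cells** — cocci as disks (default radius 4 px) and rods as
  capsules (default 14 × 4 px, uniform random orientation), at
  x40-objective-like sampling so individual cells are resolvable;
  placed uniformly at random, by default without overlap (rejection
  sampling, 200 tries per cell, failure names the density limit);
* **labels** — each cell dead with probability `frac_dead`
  (Bernoulli); live cells render into green, dead into red; an
  optional bleed-through fraction leaks dead-cell intensity into green
  (off by default to keep the truth unambiguous);
* **red haze** — low-frequency Gaussian-smoothed random blobs
  (σ = 20 px) scaled to `haze_amplitude`, mimicking propidium iodide
  bound to extracellular DNA;
* **shading** — a multiplicative illumination ramp across the field
  (default 20 % falloff);
* **noise** — additive Gaussian (default σ = 12) with an optional
  Poisson stage.

Defaults (256×256 px, 60 cells, cell intensity 180 ± 25) give a
signal-to-noise ratio of 15 and haze at ~22 % of cell intensity —
moderate density with resolvable cells. Truth masks are fixed *before*
noise and illumination are applied, so downstream error measures the
pipeline, not the generator; true viability is defined area-based,
identically to the pipeline's own definition.

What the generator does **not** emulate: confocal point-spread
blurring, 3-D matrix structure, overlapping or out-of-focus cells,
autofluorescence spectra, or dyes competing within one cell. Passing
tests on synthetic frames therefore demonstrate the algorithm's
correctness and its robustness to haze, shading and sensor noise —
they do not certify accuracy on real micrographs, where ground truth
requires manual delineation.

## Numerical choices

* Reconstruction runs in float64 on integer-valued data; convergence
  is exact (no pixel changes), so results are bit-reproducible.
* Border handling for erosion/dilation ignores out-of-bounds pixels
  (erosion pads +∞, dilation −∞): the image border creates no
  structure.
* The joint histogram always uses 256 bins over [0, 2^bit_depth − 1]:
  for 8-bit data each bin is one intensity level (the classic
  behaviour); 16-bit data is binned 256 levels per bin, which extends
  the same rule predictably.
* Thresholding uses strict inequality (> t); ties in the Otsu
  objective resolve to the lowest qualifying threshold. Both choices
  exist to make masks bit-reproducible.
* `analyze` contains no randomness at all; the generator funnels all
  randomness through one seeded `numpy` generator, and z-stack slices
  derive their seeds from the stack seed and slice index.

## Design decisions that were genuinely open

* "Structuring element of size 3" is read as *radius* 3 px (the
  ImageJ morphology convention); it is a parameter, not a constant.
* The "erosion, reconstruction and dilation" sequence is fixed as
  erode → reconstruct-by-dilation → one final clipped dilation, with
  the final dilation toggleable, since the phrase is ambiguous about
  whether "dilation" names the geodesic iterations or a separate step.
* The rolling-ball radius (50 px) is the common ImageJ default; the
  appropriate value depends on cell size in pixels and should exceed
  the largest cell footprint by a wide margin.
* The gamma direction ambiguity is resolved by implementing both
  conventions rather than guessing (see step 4 above).
* FPR is *not* computed with the occasionally-printed TP+FP
  denominator, which contradicts the identity FPR = 1 − specificity;
  the identity wins.
* Slices of a depth profile with no detected bacteria propagate NA
  viability rather than 0 or 100.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline on
256×256 synthetic frames (6 all-dead, 5 all-live, 20 recovery seeds,
10 haze pairs), oracle comparisons on 12×12–24×24 images (50–200
instances), and one batch of 25 frames at the full 512×512 acquisition
size. These sizes were chosen so a complete validation runs on a
laptop-class single core in minutes while every check still exercises
the same code path as full-size data.

## Known limitations

* Area-based viability saturates when cells overlap heavily; the
  generator's no-overlap default matches the regime the method is
  designed for (resolvable individual bacteria).
* A global threshold assumes reasonably uniform staining efficiency;
  strong per-cell intensity variation pushes faint cells below t even
  after gamma adjustment.
* The red-channel background subtraction deliberately trades red
  sensitivity for specificity: faint diffuse red (including genuinely
  dead, weakly stained cells) is removed along with haze, which can
  overestimate viability in hazy images.
* Proprietary microscope formats (CZI/LIF/ND2) and OME-XML metadata
  are not parsed; convert to TIFF first.
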