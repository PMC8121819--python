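# livedead

Automated quantification of bacterial viability and surface coverage
from live/dead-stained biofilm confocal micrographs.

Biofilms stained with SYTO 9 (green: all cells with intact membranes)
and propidium iodide (red: membrane-compromised, dead cells) are
routinely imaged by confocal laser scanning microscopy, but turning
those micrographs into numbers is usually manual, subjective and slow.
`livedead` is a scriptable reimplementation of an automated
segmentation workflow for such images, aimed at microbiologists and
biomaterials researchers evaluating antimicrobials, mouthwashes and
implant surfaces. It provides:

* a deterministic segmentation pipeline: opening-by-reconstruction
  (disk structuring element), rolling-ball background subtraction on
  the red channel (to reject extracellular-DNA haze), gamma
  adjustment, and a **single Otsu threshold computed from the pooled
  histogram of both channels**;
* area-based readouts per image, per z-slice and per batch;
* pixelwise sensitivity/specificity (ROC) validation against
  ground-truth masks;
* a synthetic micrograph generator with exact live/dead ground truth,
  so the entire pipeline is testable without real data.

## The statistic

For one two-channel image, with `t` the joint Otsu threshold applied
to both preprocessed channels:

```
dead   = |{red > t}|                    (dead-stain area, px)
total  = |{green > t} ∪ {red > t}|      (all-bacteria area, px)
% alive    = 100 · (total − dead) / total
% coverage = 100 · total / image pixels
```

`% alive` is undefined (NA) when no bacteria are detected, so blank
fields never masquerade as all-dead or all-live ones. Applied slice by
slice to a z-stack at 1 µm increments, the same two numbers give
viability and biomass profiles versus distance from the coverslip.

## Worked example

```sh
python examples/quantify_single_frame.py
```

generates a 256×256 field of cocci (60 cells, 30 % dead, red haze,
shading, sensor noise), runs the full pipeline and prints:

```
threshold            : 84
total bacterial px   : 2996
dead (red) px        : 1248
% alive (pipeline)   : 58.34
% alive (true)       : 58.34
% coverage           : 4.57
```

The threshold is the joint-Otsu cut on the pooled histogram; 2996 px
of the field were classified as bacteria, of which 1248 px are red
(dead), so 58.34 % of the stained area is alive — here matching the
generator's exact ground truth to the printed precision — and the
biofilm covers 4.57 % of the field. The other examples show a
U-shaped viability depth profile through a z-stack
(`depth_profile.py`), batch analysis from TIFFs on disk with mean/SD/CV
(`batch_from_disk.py`), and channel-wise ROC validation against truth
masks (`validate_against_truth.py`).

## Command line

The same pipeline is exposed as a thin CLI for shell use:

```sh
livedead simulate --seed 5 --out field.tif          # synthetic image + truth
livedead analyze --input 'images/*.tif' --out results.csv --summary summary.csv
livedead analyze --input stack.tif --zstack --z-step 1.0 --out profile.csv
livedead validate --pred-green g.png --pred-red r.png \
                  --truth-green tg.png --truth-red tr.png --out roc.csv
```

Every `analyze` run writes its effective parameter set (including
defaults) next to the results, and reruns are byte-identical. One
unreadable image is recorded as an error row and never aborts the
batch.

## Scope

The package quantifies area, not discrete cells: no instance
segmentation, cell counting, biovolume or inter-group hypothesis
testing (export the per-sample CSV and use your statistics tool of
choice). Proprietary microscope formats are not read; convert to TIFF.
See `docs/methods.md` for the model, parameter meanings, generator
assumptions and known limitations.
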