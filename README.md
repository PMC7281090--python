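# silverquant

Quantification of silver-enhanced gold-nanoparticle (AuNP) deposits in
histological sections.

Antibody-functionalized AuNPs accumulate in tumors and organs; after
silver-enhancement staining each deposit appears as a dark,
high-optical-density blob on a Nuclear-Fast-Red counterstained section.
`silverquant` turns calibrated section images into per-organ
biodistribution numbers:

* **positive pixels per mm²** of delineated tissue and **percent
  positive per section**,
* **deposit-size distributions** (µm²) from connected-component
  analysis of individual silver spots,

via a weak-supervision pipeline: color-specific dynamic thresholding
with morphological cleanup bootstraps training masks, a small U-Net
(numpy + numba, no GPU needed) is trained on them under a slide-level
k-fold rotation so every slide is segmented by a model that never saw
it, and overlapping patches are re-concatenated by center-crop ownership
so nothing is counted twice. A synthetic histology generator with exact
per-pixel ground truth stands in for scanned slides and makes every
stage verifiable end to end. See `docs/methods.md` for the model and its
assumptions.

Intended users: image-analysis folks in nanomedicine / digital pathology
who need a reproducible, fully testable reference implementation of this
class of pipeline.

## Worked example

```python
import numpy as np
from silverquant import (
    SyntheticSpec, render_section, ROIMask, ThresholdParams,
    weak_label, components, quantify_density, size_histogram,
)

# one calibrated synthetic section: 512×512 px at 0.25 µm/px (0.0164 mm²)
spec = SyntheticSpec(dims=(512, 512), mpp=0.25, deposit_density=1200.0, seed=7)
image, truth = render_section(spec, organ_label="tumor", slide_id="tumor_00")

# threshold bootstrap on the whole section
mask = weak_label(image.pixels, ThresholdParams())
roi = ROIMask(np.ones(image.dims, bool))
d = quantify_density(mask, roi, image.mpp)
table = components(mask, image.mpp, slide_id=image.slide_id)
hist = size_histogram(table)

print(f"{d.positive_px_per_mm2:,.0f} positive px/mm2 ({d.percent_positive:.2f}%)")
print(f"{len(table)} deposits, dominant size class {hist.bin_label(hist.dominant_bin)}")
print(f"ground truth: {truth.positive_pixels} px, {len(truth.components)} deposits")
```

prints

```
326,233 positive px/mm2 (2.04%)
19 deposits, dominant size class [10, 50) um2
ground truth: 5528 px, 23 deposits
```

i.e. the bootstrap alone recovers a ~2 %-positive tumor section with 19
of 23 planted deposits (the misses are the palest spots cut by the
luminance cap), and the dominant size class is the 10–50 µm² bin that
contains the 25 µm² aggregate mode.

The full experiment — 42 slides, 7 organs, fold-rotated training,
per-organ report — runs from the command line:

```sh
silverquant run --seed 1 --out runs/demo        # all stages, ~15 min on one CPU
silverquant simulate --seed 1 --out cohort/     # just the synthetic cohort
```

`runs/demo/report.csv` then holds mean ± sd positive px/mm² and percent
positive per organ plus each organ's dominant deposit-size class, with
tumor ranked first; `slides.csv` holds per-slide IoUs of both the
network and the weak-label baseline against ground truth.

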