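# Methods

## Problem

Antibody-functionalized gold nanoparticles (AuNPs) injected into
tumor-bearing animals are visualized in histological sections by silver
enhancement: metallic silver grows on the gold cores and renders each
deposit as a dark, high-optical-density blob against a Nuclear-Fast-Red
counterstained background. Quantifying the biodistribution means turning
calibrated section images into, per organ, (a) positive pixels per mm²
of delineated tissue, (b) percent-positive area per section, and (c) a
size distribution of individual deposits obtained by connected-component
analysis. Densities of interest span three orders of magnitude (tumor ≫
spleen/liver ≫ heart), and deposit areas are strongly bimodal: a ~1 µm²
class (endosomal/organelle scale, single cells) and a ~25 µm² class
(macrophage-scale aggregates).

## Pipeline

The quantification runs in four stages, orchestrated by one config and
one master seed.

1. **Weak-label bootstrap.** Each delineated region is tiled into
   slightly overlapping square patches. A pixel of a patch is
   weak-positive when it is *dark* — luminance `(R+G+B)/3` at or below
   `min(dynamic cut, max_luminance)`, where the dynamic cut is the
   patch's low luminance percentile (default 5 %) and the cap defaults
   to 110/255 — *and* *achromatic* — red/green ratio below 1.35, which
   vetoes the red-dominant counterstain even where nuclei stain darkly.
   The raw mask is cleaned by morphological opening then closing with
   fixed 3×3 square kernels (outside the image counts as background).
   A small grid of threshold parameterizations is evaluated per patch
   and the candidate with the highest mean pairwise IoU against the
   others is selected (ties toward fewer positives). Explicit correction
   masks, when supplied, override the selection verbatim — the hook that
   preserves manual corrections as data.

2. **Learned segmentation under slide-level fold rotation.** Slides are
   partitioned into k = 3 folds (never patch-level: patches of one slide
   are correlated). For each rotation a U-Net-style encoder/decoder is
   trained on the weak labels of the k−1 training folds and applied only
   to the held-out fold, so every slide is segmented by a model that
   never saw it. The architecture has 4 encoder levels doubling the
   feature channels from the base count (16 by default, bottleneck 256);
   decoder stages upsample, reduce channels 1×1, concatenate the encoder
   skip and fuse 3×3. The loss is pixelwise binary cross-entropy on
   logits; optimization is Adam with a half-cosine learning-rate decay
   over 10 epochs. The network is implemented directly on numpy with
   numba-compiled convolution kernels; no GPU or deep-learning framework
   is involved, which keeps training deterministic given the seed.

3. **Stitching without double counting.** Patch probability masks are
   binarized (threshold 0.5) and re-concatenated by *center-crop
   ownership*: every section pixel takes its value from exactly one
   patch — the one whose center is nearest, ties to the earlier anchor
   in row-major order. This makes stitching a left inverse of tiling
   (`stitch(crops(M)) = M` bit-exactly), which is the testable form of
   "no boundary effects, no double counting". Binarization separates
   detection from delineation. Detection: connected regions of the
   stitched probability field at p ≥ 0.5, filtered for sub-resolution
   noise — detections smaller than 4 px (0.25 µm² at the default
   calibration, below the smallest reportable deposit area) are
   discarded, and detections smaller than 8 px must contain a pixel with
   p ≥ 0.65 (real deposits the model finds always have such a confident
   core; threshold-grazing speckle does not). Delineation: each kept
   detection is extended into its connected p ≥ 0.3 halo (Canny-style
   hysteresis), because a hard cut on soft probability edges erodes
   every deposit by its outermost ring — a systematic ~10 % area bias
   that also misplaces the ~1 µm² class in the size histogram. All
   constants are config knobs.

4. **Quantification.** Connected components under 8-connectivity
   (diagonal contact = one physical aggregate; 4-connectivity is a
   config option) yield per-deposit pixel counts and areas
   `pixel_count × mpp²` in µm². Densities divide in-ROI positive pixels
   by ROI area in mm²; percent-positive divides by the ROI pixel count —
   the ROI is the only delineated object, so it is the denominator for
   both. Size histograms use left-closed right-open µm² bins with edges
   0.25/0.5/2/10/50/200/∞, bracketing the 1 µm² and 25 µm² classes;
   areas below 0.25 µm² are folded into the first bin. The per-organ
   report gives mean ± sd over replicate slides (sd = 0 for singletons)
   and a pooled histogram whose dominant bin is the count arg-max, ties
   resolved toward the larger-area bin.

## Synthetic cohort

No imaging data accompany the study, so a generator produces calibrated
pseudo-sections with exact ground truth; its defaults define the test
conditions for the whole package.

* **Geometry.** Deposits are rasterized ellipses (pixel-center rule,
  eccentricity uniform in [0, 0.8]) whose areas are drawn from a
  two-component log-normal mixture with medians 25 µm² and 1 µm²
  (log-sd 0.35). Deposits are placed by rejection sampling with an
  8-neighbourhood separation of at least one pixel, so ground-truth
  component counts are exact by construction; deposit counts are Poisson
  in the expected `density × area`, with a fixed-count override for
  exact-count tests.
* **Calibration.** Default 0.25 µm/px (a 40×-scan-equivalent
  resolution), chosen so the 1 µm² deposit class spans ≥ 16 px and is
  therefore resolvable by the fixed 3×3 morphology kernels rather than
  erased by them.
* **Appearance.** Background is a low-frequency blend of two pink tones
  (tissue and counterstain) plus two distractor classes: small dark-pink
  nuclear speckle whose red-dominance is jittered toward the ratio veto,
  and achromatic pigment-like debris (the anthracotic / formalin-pigment
  class of brightfield confounders) whose luminance straddles the
  darkness cap. Deposits are dark and achromatic with a per-slide
  silver-development factor (sd 0.12, clipped to [0.8, 1.3]),
  per-deposit darkness jitter (sd 0.20) and radial rim brightening
  (+22/255 at the rim). Gaussian channel noise (sd 6) is added last and
  never perturbs geometry, so the ground-truth mask is exactly the
  pre-noise deposit union. The debris is what makes a darkness threshold
  genuinely imperfect — its darker tail is indistinguishable from silver
  by luminance and chroma alone, so the bootstrap false-positives on it
  while the learned stage can reject it — and the mild development
  variability adds the slide-level drift that fixed global parameters
  cannot follow. Together they reproduce, in controlled form, the two
  reasons the learned stage outperforms its own bootstrap on real
  silver-enhanced sections.
* **Organ presets.** Densities (deposits/mm²) and large-class weights:
  tumor 1200/0.70, spleen 300/0.60, liver 240/0.55, intestine 190/0.35,
  lung 150/0.30, kidney 80/0.25, heart 8/0.30. Expected positive-area
  ranking is strictly decreasing in this order (verified in closed form
  as `density × E[area]`); tumor sits near 2 % positive area and heart
  near the detection floor. Gaps between adjacent organs are kept at
  ≥ ~1.3× so the ranking is resolvable at desk-scale section areas;
  with the study-scale spleen/liver gap of only ~5 % no raster
  experiment of this size could resolve the order reliably.
* **Not modelled.** Nuclei instances, staining physics, scanner optics,
  compression artifacts, tissue folds, and anisotropic sampling. Passing
  tests therefore demonstrate correctness of the measurement chain and
  the weak-label → network bootstrap under controlled variability, not
  performance on any real scanner's output.

## Desk-scale defaults and problem sizes

The default experiment is sized for a single CPU: 7 organs × 6
replicates = 42 slides of 512×512 px at 0.25 µm/px (0.0164 mm² each),
tiling patches of 128 px with 32 px overlap, training tiles of 64 px,
~800 training tiles per rotation, 10 epochs, base channel count 8. The
architecture default elsewhere in the package remains 4 levels / base 16
(bottleneck 256); the experiment config narrows the base to 8 and the
patch edge to 64 purely as a scale choice — the contracts (fold
rotation, stitching semantics, quantification) are scale-free and are
tested as such. A faithful-scale run (1000 px patches, ~5000 training
patches, base 16) is a config change, not a code change.

## Numerical choices and edge cases

* IoU of two empty masks is defined as 1 (agreement on absence).
* Consensus selection with a single candidate returns it unchanged.
* The red/green ratio uses a green floor of 1 so it is defined on black.
* Fold sizes differ by at most one slide; the assignment is a seeded
  permutation with round-robin fill, deterministic per seed.
* Empty-ground-truth organs are compared at an absolute detection floor
  (0.02 % positive) instead of a relative error, which would be
  undefined at zero.
* Probability masks are binarized at 0.5; the threshold is exposed in
  the config, as no principled default exists beyond symmetry.
* All randomness flows from one master seed: cohort slides get child
  seeds via `SeedSequence` spawning; each rotation trains with seed
  `master*1000 + rotation`.

## Known limitations

* The weak-label dialect (percentile cut + cap + ratio veto) is one of
  several defensible readings of color-specific dynamic thresholding;
  its parameters were tuned for the default palette, mirroring how such
  thresholds are tuned per staining batch in practice.
* The per-patch percentile component caps the positive fraction a patch
  can reach, so the bootstrap systematically under-segments very dense
  patches; the learned stage compensates, which is visible in the
  tumor-slide IoUs.
* Components clipped by the ROI boundary are counted with their in-ROI
  area only (dropping them instead is available via
  ``exclude_border``/`--exclude-border-components`); no edge correction
  is applied to the size histogram.
* Training is single-threaded float32; loss trajectories are
  reproducible on one platform but may differ in the last digits across
  BLAS builds.
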