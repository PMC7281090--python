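"""Weak-label bootstrapping by color-specific dynamic thresholding.

The preliminary segmentation marks a pixel as silver-positive when it is
both dark and achromatic:

* **dark** — luminance ``(R+G+B)/3`` at or below the smaller of a
  per-patch dynamic cut (the patch's low luminance percentile) and an
  absolute 8-bit cap;
* **achromatic** — red/green ratio below a veto threshold, which
  excludes the red-dominant Nuclear Fast Red counterstain even where it
  is dark (dense nuclear speckle).

The raw mask is then cleaned by morphological opening (speckle removal)
followed by closing (pinhole bridging) with fixed square kernels.
Everything outside the image border counts as background for the
morphology.

The ``select_mask``/``select_masks`` step stands in for the study's
manual selection among candidate parameterizations: it picks, per
patch, the candidate with the highest mean pairwise IoU against the
other candidates (consensus), and accepts explicit correction masks
verbatim — the hook that preserves manual corrections as data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BinaryMask, ValidationError
from .quantify import iou

__all__ = ["ThresholdParams", "weak_label", "select_mask", "select_masks"]


@dataclass(frozen=True)
class ThresholdParams:
    """Dynamic-threshold and morphology parameters.

    ``luminance_percentile`` — per-patch dark-pixel percentile cut (%);
    ``max_luminance`` — absolute cap in 8-bit units; ``min_channel_ratio``
    — red/green ratio at or above which dark pixels are treated as
    counterstain; ``open_kernel``/``close_kernel`` — odd square kernel
    sides in px.
    """

    luminance_percentile: float = 5.0
    max_luminance: float = 110.0
    min_channel_ratio: float = 1.35
    open_kernel: int = 3
    close_kernel: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.luminance_percentile <= 50):
            raise ValidationError("luminance_percentile must be in (0, 50]")
        if not (0 < self.max_luminance < 255):
            raise ValidationError("max_luminance must be in (0, 255)")
        for k in (self.open_kernel, self.close_kernel):
            if k < 1 or k % 2 == 0:
                raise ValidationError("kernels must be odd and >= 1")


def weak_label(patch: np.ndarray, params: ThresholdParams) -> BinaryMask:
    """Threshold + morphology weak segmentation of one RGB patch.

    The red/green ratio uses a green floor of 1 to stay defined on black
    pixels.  Returns a mask with provenance ``weak_label``.
    """
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3 or patch.dtype != np.uint8:
        raise ValidationError("patch must be H×W×3 uint8")
    rgb = patch.astype(np.float64)
    lum = rgb.sum(axis=2) / 3.0
    cut = min(np.percentile(lum, params.luminance_percentile), params.max_luminance)
    ratio = rgb[:, :, 0] / np.maximum(rgb[:, :, 1], 1.0)
    raw = (lum <= cut) & (ratio < params.min_channel_ratio)
    if params.open_kernel > 1:
        raw = ndimage.binary_opening(
            raw, structure=np.ones((params.open_kernel,) * 2, bool)
        )
    if params.close_kernel > 1:
        raw = ndimage.binary_closing(
            raw, structure=np.ones((params.close_kernel,) * 2, bool)
        )
    return BinaryMask(raw, provenance="weak_label")


def select_mask(
    candidates: list[tuple[ThresholdParams, BinaryMask]],
    correction: BinaryMask | None = None,
) -> tuple[int, BinaryMask]:
    """Consensus selection among candidate weak masks for one patch.

    Returns ``(winner_index, mask)``.  The winner maximizes the mean
    pairwise IoU against the other candidates; ties break toward the
    smallest positive-pixel count (the conservative reading).  A
    ``correction`` mask, when given, overrides the selection verbatim
    and is returned with index ``-1``.
    """
    if correction is not None:
        return -1, correction
    if not candidates:
        raise ValidationError("empty candidate list")
    if len(candidates) == 1:
        return 0, candidates[0][1]
    masks = [m for _, m in candidates]
    n = len(masks)
    scores = np.zeros(n)
    for i in range(n):
        scores[i] = np.mean([iou(masks[i], masks[j]) for j in range(n) if j != i])
    best = max(
        range(n), key=lambda i: (scores[i], -int(masks[i].mask.sum()), -i)
    )
    return best, masks[best]


def select_masks(
    candidates_per_patch: list[list[tuple[ThresholdParams, BinaryMask]]],
    corrections: dict[int, BinaryMask] | None = None,
) -> list[BinaryMask]:
    """Apply :func:`select_mask` per patch; ``corrections`` maps patch
    index → override mask."""
    corrections = corrections or {}
    out = []
    for i, cands in enumerate(candidates_per_patch):
        _, mask = select_mask(cands, corrections.get(i))
        out.append(mask)
    return out
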