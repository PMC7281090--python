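"""Patch tiling of ROIs with the bookkeeping that makes stitching exact.

Sections are subdivided into fixed-size, slightly overlapping square
patches.  Anchors advance with stride ``patch_size - overlap``; the last
anchor per axis is clamped so its patch ends exactly at the (padded)
image edge, and images smaller than one patch are padded bottom/right
with a recorded extent so the stitched result can be cropped back
losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CalibratedImage, ROIMask, ValidationError

__all__ = ["TilingSpec", "PatchGrid", "plan_tiles", "extract_patch"]


@dataclass(frozen=True)
class TilingSpec:
    """Patch geometry: size, overlap and out-of-image fill color."""

    patch_size: int = 1000
    overlap: int = 100
    pad_value: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if not (0 < self.overlap < self.patch_size):
            raise ValidationError(
                f"need 0 < overlap < patch_size, got {self.overlap}/{self.patch_size}"
            )


@dataclass
class PatchGrid:
    """Tiling plan for one slide."""

    slide_id: str
    anchors: list[tuple[int, int]]  # (row, col) top-left, row-major order
    patch_size: int
    overlap: int
    image_dims: tuple[int, int]  # original (pre-padding) dims
    padded_dims: tuple[int, int]
    pad_extent: tuple[int, int]  # (bottom, right) padding in px
    pad_value: tuple[int, int, int] = (255, 255, 255)

    def __len__(self) -> int:
        return len(self.anchors)


def _axis_anchors(dim: int, patch: int, stride: int) -> list[int]:
    last = dim - patch
    anchors = list(range(0, last + 1, stride))
    if anchors[-1] != last:
        anchors.append(last)
    return anchors


def plan_tiles(
    image_dims: tuple[int, int],
    roi: ROIMask,
    spec: TilingSpec,
    slide_id: str = "",
) -> PatchGrid:
    """Plan a patch grid covering the ROI.

    Patches whose footprint lies fully outside the ROI bounding box are
    omitted; every ROI pixel is covered by at least one patch.
    """
    if roi.pixel_count == 0:
        raise ValidationError("empty ROI")
    if roi.mask.shape != tuple(image_dims):
        raise ValidationError("ROI shape does not match image dims")
    h, w = image_dims
    p = spec.patch_size
    stride = p - spec.overlap
    ph, pw = max(h, p), max(w, p)
    pad = (ph - h, pw - w)

    rows = _axis_anchors(ph, p, stride)
    cols = _axis_anchors(pw, p, stride)

    rr, cc = np.nonzero(roi.mask)
    r0, r1 = rr.min(), rr.max()
    c0, c1 = cc.min(), cc.max()
    anchors = [
        (ar, ac)
        for ar in rows
        for ac in cols
        if ar <= r1 and ar + p > r0 and ac <= c1 and ac + p > c0
    ]
    return PatchGrid(
        slide_id=slide_id,
        anchors=anchors,
        patch_size=p,
        overlap=spec.overlap,
        image_dims=(h, w),
        padded_dims=(ph, pw),
        pad_extent=pad,
        pad_value=spec.pad_value,
    )


def extract_patch(
    image: CalibratedImage | np.ndarray, grid: PatchGrid, index: int
) -> np.ndarray:
    """Extract patch ``index`` as a ``patch_size²×3`` uint8 array.

    Out-of-image area (from edge padding) is filled with the grid's
    ``pad_value``.
    """
    if not (0 <= index < len(grid.anchors)):
        raise IndexError(f"patch index {index} out of range 0..{len(grid.anchors) - 1}")
    pixels = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    h, w = grid.image_dims
    if pixels.shape[:2] != (h, w):
        raise ValidationError("image dims do not match the grid")
    p = grid.patch_size
    ar, ac = grid.anchors[index]
    patch = np.empty((p, p, 3), dtype=np.uint8)
    patch[:] = np.asarray(grid.pad_value, dtype=np.uint8)
    r1 = min(ar + p, h)
    c1 = min(ac + p, w)
    patch[: r1 - ar, : c1 - ac] = pixels[ar:r1, ac:c1]
    return patch
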