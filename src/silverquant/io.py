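"""Calibrated image, ROI and mask I/O.

Conventions used throughout the package
---------------------------------------
* Pixel grids are 0-based, row-major ``(row, col)`` numpy arrays.
* Polygon vertices are given as ``(x, y)`` pairs in pixel units, where
  ``x`` indexes columns and ``y`` indexes rows.
* Pixel centers sit at integer coordinates + 0.5; a pixel belongs to a
  polygon when its center lies inside the closed polygon under the
  even-odd rule.
* Physical calibration is a single isotropic microns-per-pixel value
  (``mpp``); all areas derive from it as ``pixel_count * mpp**2`` µm².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "CalibratedImage",
    "ROIMask",
    "BinaryMask",
    "ValidationError",
    "load_image",
    "save_image",
    "rasterize_roi",
    "load_roi",
    "save_mask",
    "load_mask",
    "save_polygon_json",
    "load_polygon_json",
]

MaskProvenance = Literal["ground_truth", "weak_label", "predicted"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class CalibratedImage:
    """An 8-bit RGB section image with physical calibration.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    mpp
        Microns per pixel, isotropic, strictly positive.
    organ_label
        Free-text organ name (e.g. ``"tumor"``, ``"spleen"``).
    slide_id
        Unique slide identifier.
    """

    pixels: np.ndarray
    mpp: float
    organ_label: str = ""
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(
                f"expected an H×W×3 pixel grid, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError("image must have at least one pixel")
        if self.pixels.dtype != np.uint8:
            raise ValidationError(
                f"expected 8-bit channels, got dtype {self.pixels.dtype}"
            )
        if not (self.mpp > 0):
            raise ValidationError(f"mpp must be > 0, got {self.mpp}")

    @property
    def dims(self) -> tuple[int, int]:
        """Image height and width in pixels."""
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def area_mm2(self) -> float:
        """Physical image area in mm²."""
        h, w = self.dims
        return h * w * self.mpp**2 / 1e6


@dataclass
class ROIMask:
    """Region-of-interest mask aligned to a :class:`CalibratedImage`."""

    mask: np.ndarray
    source: Literal["polygon", "raster"] = "raster"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("ROI mask must be a 2-D boolean grid")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class BinaryMask:
    """Per-pixel positive/negative labels with provenance."""

    mask: np.ndarray
    provenance: MaskProvenance = "predicted"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("binary mask must be a 2-D boolean grid")


def _decode_8bit_rgb(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.dtype != np.uint8:
        raise ValidationError(
            f"{path}: unsupported bit depth {arr.dtype}; 8-bit input required"
        )
    if arr.ndim == 2:  # grayscale replicated to three channels
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3:
        raise ValidationError(f"{path}: expected a 2-D or 3-D image, got {arr.ndim}-D")
    if arr.shape[2] > 3:
        raise ValidationError(
            f"{path}: image has {arr.shape[2]} channels; at most 3 supported"
        )
    if arr.shape[2] < 3:
        raise ValidationError(f"{path}: image has {arr.shape[2]} channels; need 1 or 3")
    return np.ascontiguousarray(arr)


def load_image(
    path: str | Path, mpp: float, organ_label: str = "", slide_id: str = ""
) -> CalibratedImage:
    """Read an 8-bit RGB TIFF or PNG as a :class:`CalibratedImage`.

    Grayscale input is replicated to three channels.  Anything other than
    8-bit data is rejected; ``mpp`` is required user metadata and never
    inferred from file headers.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if not (mpp > 0):
        raise ValidationError(f"mpp must be > 0, got {mpp}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB"):
                # 16-bit ("I;16") and palette/alpha modes are out of contract
                if im.mode in ("I", "I;16", "I;16B", "F"):
                    raise ValidationError(
                        f"{path}: unsupported bit depth (mode {im.mode}); "
                        "8-bit input required"
                    )
                im = im.convert("RGB")
            arr = np.asarray(im)
    arr = _decode_8bit_rgb(np.asarray(arr), path)
    return CalibratedImage(arr, mpp=mpp, organ_label=organ_label, slide_id=slide_id)


def save_image(image: CalibratedImage, path: str | Path) -> None:
    """Write the pixel grid as PNG or TIFF (by extension), losslessly."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        Image.fromarray(image.pixels, mode="RGB").save(path)


def rasterize_roi(
    polygon_vertices: Sequence[Sequence[float]], image_dims: tuple[int, int]
) -> ROIMask:
    """Rasterize a closed polygon into a boolean ROI mask.

    A pixel is inside when its center ``(col + 0.5, row + 0.5)`` lies
    inside the polygon under the even-odd (crossing-number) rule, so
    self-intersecting delineations are accepted and resolved like any
    drawing program would.

    Parameters
    ----------
    polygon_vertices
        At least three ``(x, y)`` pairs in pixel units.
    image_dims
        ``(H, W)`` of the target grid.
    """
    verts = np.asarray(polygon_vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValidationError(
            f"polygon needs >= 3 (x, y) vertices, got shape {verts.shape}"
        )
    h, w = image_dims
    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    px, py = np.meshgrid(xs, ys)  # (H, W)

    # even-odd rule: count edge crossings of a horizontal ray to +x
    inside = np.zeros((h, w), dtype=bool)
    x0, y0 = verts[:, 0], verts[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    for ax, ay, bx, by in zip(x0, y0, x1, y1):
        if ay == by:
            continue  # horizontal edge never crosses the ray
        straddles = (ay > py) != (by > py)
        with np.errstate(invalid="ignore"):
            x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= straddles & (px < x_cross)
    return ROIMask(inside, source="polygon")


def load_roi(path: str | Path, image_dims: tuple[int, int]) -> ROIMask:
    """Load an ROI from a polygon JSON or a raster mask image."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        _, verts = load_polygon_json(path)
        return rasterize_roi(verts, image_dims)
    m = load_mask(path)
    if m.mask.shape != tuple(image_dims):
        raise ValidationError(
            f"ROI raster shape {m.mask.shape} does not match image dims {image_dims}"
        )
    return ROIMask(m.mask, source="raster")


def save_mask(mask: BinaryMask | ROIMask, path: str | Path) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG (lossless)."""
    arr = (np.asarray(mask.mask, dtype=np.uint8)) * 255
    try:
        Image.fromarray(arr, mode="L").save(Path(path))
    except OSError as exc:
        raise IOError(f"cannot write mask to {path}: {exc}") from exc


def load_mask(
    path: str | Path, provenance: MaskProvenance = "predicted"
) -> BinaryMask:
    """Read a 0/255 single-channel PNG back into a :class:`BinaryMask`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"mask file not found: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValidationError(f"{path}: mask must be single-channel")
    return BinaryMask(arr > 127, provenance=provenance)


def save_polygon_json(
    slide_id: str, vertices: Sequence[Sequence[float]], path: str | Path
) -> None:
    """Persist an ROI delineation as JSON (pixel-unit vertices)."""
    payload = {
        "slide_id": slide_id,
        "vertices": [[float(x), float(y)] for x, y in vertices],
        "units": "pixel",
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_polygon_json(path: str | Path) -> tuple[str, list[list[float]]]:
    payload = json.loads(Path(path).read_text())
    if payload.get("units", "pixel") != "pixel":
        raise ValidationError(f"{path}: polygon units must be 'pixel'")
    return payload["slide_id"], payload["vertices"]
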