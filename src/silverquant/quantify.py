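"""Deposit-level and section-level quantification.

Turns binary AuNP masks into the reported biodistribution quantities:
individual deposits via connected-component analysis, positive-pixel
densities per mm² of ROI, percent-positive per section, and deposit-size
histograms per organ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .io import BinaryMask, ROIMask, ValidationError

__all__ = [
    "COMPONENT_COLUMNS",
    "DEFAULT_BIN_EDGES",
    "DensityStats",
    "SizeHistogram",
    "BiodistributionReport",
    "components",
    "quantify_density",
    "size_histogram",
    "build_report",
    "iou",
]

COMPONENT_COLUMNS = [
    "component_id",
    "slide_id",
    "pixel_count",
    "area_um2",
    "centroid_row",
    "centroid_col",
    "bbox_row0",
    "bbox_col0",
    "bbox_row1",
    "bbox_col1",
]

# µm² bin edges bracketing the ~1 µm² (single-cell organelle scale) and
# ~25 µm² (macrophage-scale aggregate) deposit classes; last bin open.
DEFAULT_BIN_EDGES = (0.25, 0.5, 2.0, 10.0, 50.0, 200.0, np.inf)


def empty_component_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        COMPONENT_COLUMNS,
        [int, str, int, float, float, float, int, int, int, int],
    )})


def components(
    mask: BinaryMask,
    mpp: float,
    slide_id: str = "",
    connectivity: int = 2,
    roi: ROIMask | None = None,
    exclude_border: bool = False,
) -> pd.DataFrame:
    """Label individual deposits and tabulate their physical sizes.

    Uses 8-connectivity by default (``connectivity=2``): silver deposits
    are compact, so diagonal contact is read as one physical aggregate.
    Component ids are deterministic, ordered by bounding-box top-left
    ``(row, col)``.

    When an ``roi`` is given, components are clipped to it and counted
    with their in-ROI area only; with ``exclude_border`` set, components
    touching the ROI boundary (i.e. clipped ones, whose true size is
    unknowable) are dropped instead — an explicit choice for size
    statistics at the cost of density completeness.

    Returns a DataFrame with :data:`COMPONENT_COLUMNS`; ``area_um2`` is
    ``pixel_count * mpp**2``.
    """
    if not (mpp > 0):
        raise ValidationError(f"mpp must be > 0, got {mpp}")
    if connectivity not in (1, 2):
        raise ValidationError("connectivity must be 1 (4-conn) or 2 (8-conn)")
    grid = mask.mask
    if roi is not None:
        if roi.mask.shape != grid.shape:
            raise ValidationError("ROI shape does not match mask")
        clipped = grid & roi.mask
        if exclude_border:
            from scipy import ndimage

            outside = ~roi.mask
            # pad so image edges count as outside-ROI too
            padded = np.pad(clipped, 1)
            out_pad = np.pad(outside, 1, constant_values=True)
            labels_all, n_all = ndimage.label(
                padded, structure=np.ones((3, 3), bool)
            )
            touches = np.unique(
                labels_all[ndimage.binary_dilation(out_pad, np.ones((3, 3), bool))]
            )
            keep = np.ones(n_all + 1, dtype=bool)
            keep[0] = False
            keep[touches[touches > 0]] = False
            clipped = keep[labels_all][1:-1, 1:-1]
        grid = clipped
    labels = measure.label(grid, connectivity=connectivity)
    props = measure.regionprops(labels)
    if not props:
        return empty_component_table()
    order = sorted(range(len(props)), key=lambda i: (props[i].bbox[0], props[i].bbox[1]))
    rows = []
    for new_id, i in enumerate(order, start=1):
        p = props[i]
        r0, c0, r1, c1 = p.bbox
        rows.append(
            {
                "component_id": new_id,
                "slide_id": slide_id,
                "pixel_count": int(p.area),
                "area_um2": float(p.area) * mpp**2,
                "centroid_row": float(p.centroid[0]),
                "centroid_col": float(p.centroid[1]),
                "bbox_row0": r0,
                "bbox_col0": c0,
                "bbox_row1": r1,
                "bbox_col1": c1,
            }
        )
    return pd.DataFrame(rows, columns=COMPONENT_COLUMNS)


@dataclass
class DensityStats:
    """Per-slide positive-pixel density summary.

    ``positive_px_per_mm2`` counts mask-positive pixels inside the ROI per
    mm² of ROI area; ``percent_positive`` is the same count over the ROI
    pixel count, × 100.
    """

    slide_id: str
    organ_label: str
    positive_px_per_mm2: float
    percent_positive: float
    roi_area_mm2: float
    positive_pixels: int
    roi_pixels: int


def quantify_density(
    mask: BinaryMask, roi: ROIMask, mpp: float, organ_label: str = "", slide_id: str = ""
) -> DensityStats:
    """Positive-pixel density and percent-positive within an ROI.

    Positive pixels outside the ROI are excluded; the percent-positive
    denominator is the ROI pixel count (the only delineated object).
    """
    if not (mpp > 0):
        raise ValidationError(f"mpp must be > 0, got {mpp}")
    if mask.mask.shape != roi.mask.shape:
        raise ValidationError(
            f"mask shape {mask.mask.shape} != ROI shape {roi.mask.shape}"
        )
    roi_px = int(roi.mask.sum())
    if roi_px == 0:
        raise ValidationError("empty ROI")
    pos_px = int((mask.mask & roi.mask).sum())
    roi_area_mm2 = roi_px * mpp**2 / 1e6
    return DensityStats(
        slide_id=slide_id,
        organ_label=organ_label,
        positive_px_per_mm2=pos_px / roi_area_mm2,
        percent_positive=100.0 * pos_px / roi_px,
        roi_area_mm2=roi_area_mm2,
        positive_pixels=pos_px,
        roi_pixels=roi_px,
    )


@dataclass
class SizeHistogram:
    """Deposit-size histogram over µm² bins (left-closed, right-open)."""

    bin_edges: tuple[float, ...]
    counts: np.ndarray
    summed_area_um2: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.counts.sum())

    @property
    def dominant_bin(self) -> int:
        """Index of the modal bin; ties resolved toward the larger-area bin."""
        c = self.counts
        best = int(np.flatnonzero(c == c.max())[-1])
        return best

    def bin_label(self, i: int) -> str:
        lo, hi = self.bin_edges[i], self.bin_edges[i + 1]
        hi_s = "inf" if np.isinf(hi) else f"{hi:g}"
        return f"[{lo:g}, {hi_s}) um2"


def size_histogram(
    table: pd.DataFrame, bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
) -> SizeHistogram:
    """Bin component areas (µm²) into left-closed right-open size classes.

    Areas below the first edge land in an implicit underflow handled by
    extending the first bin to 0; the final edge may be ``inf``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be strictly ascending, length >= 2")
    areas = table["area_um2"].to_numpy(dtype=float) if len(table) else np.empty(0)
    # np.histogram closes the last bin on the right; with an inf edge this
    # matches the left-closed right-open contract for finite areas.
    full_edges = np.concatenate([[0.0], edges]) if edges[0] > 0 else edges
    counts, _ = np.histogram(areas, bins=full_edges)
    sums, _ = np.histogram(areas, bins=full_edges, weights=areas)
    if edges[0] > 0:
        # fold the underflow into the first reported bin
        counts = np.concatenate([[counts[0] + counts[1]], counts[2:]])
        sums = np.concatenate([[sums[0] + sums[1]], sums[2:]])
    reported_edges = tuple(edges)
    return SizeHistogram(
        bin_edges=reported_edges,
        counts=counts.astype(int),
        summed_area_um2=sums.astype(float),
    )


@dataclass
class OrganSummary:
    organ_label: str
    n_slides: int
    mean_px_per_mm2: float
    sd_px_per_mm2: float
    mean_percent_positive: float
    sd_percent_positive: float
    histogram: SizeHistogram
    dominant_bin_label: str


@dataclass
class BiodistributionReport:
    """Per-organ biodistribution summary over replicate slides."""

    organs: dict[str, OrganSummary] = field(default_factory=dict)

    def ranking(self) -> list[str]:
        """Organ labels sorted by decreasing mean positive px/mm²."""
        return sorted(
            self.organs, key=lambda o: self.organs[o].mean_px_per_mm2, reverse=True
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.ranking():
            s = self.organs[o]
            rows.append(
                {
                    "organ": o,
                    "n_slides": s.n_slides,
                    "mean_px_per_mm2": s.mean_px_per_mm2,
                    "sd_px_per_mm2": s.sd_px_per_mm2,
                    "mean_percent_positive": s.mean_percent_positive,
                    "sd_percent_positive": s.sd_percent_positive,
                    "dominant_size_bin": s.dominant_bin_label,
                    "n_components": s.histogram.n_components,
                }
            )
        return pd.DataFrame(rows)


def build_report(
    stats: list[DensityStats],
    tables: list[pd.DataFrame],
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> BiodistributionReport:
    """Aggregate per-slide densities and component tables per organ.

    Mean ± sd of density over replicate slides (sd = 0 for a single
    slide); one pooled size histogram per organ with a dominant-bin
    label (count arg-max, ties toward the larger-area bin).
    """
    if not stats:
        raise ValidationError("no slides to report")
    by_organ: dict[str, list[DensityStats]] = {}
    for s in stats:
        by_organ.setdefault(s.organ_label, []).append(s)
    slide_organ = {s.slide_id: s.organ_label for s in stats}
    tables_by_organ: dict[str, list[pd.DataFrame]] = {o: [] for o in by_organ}
    for t in tables:
        if len(t) == 0:
            continue
        organ = slide_organ.get(t["slide_id"].iloc[0])
        if organ is not None:
            tables_by_organ[organ].append(t)

    report = BiodistributionReport()
    for organ, slides in by_organ.items():
        dens = np.array([s.positive_px_per_mm2 for s in slides])
        pct = np.array([s.percent_positive for s in slides])
        pooled = (
            pd.concat(tables_by_organ[organ], ignore_index=True)
            if tables_by_organ[organ]
            else empty_component_table()
        )
        hist = size_histogram(pooled, bin_edges)
        report.organs[organ] = OrganSummary(
            organ_label=organ,
            n_slides=len(slides),
            mean_px_per_mm2=float(dens.mean()),
            sd_px_per_mm2=float(dens.std(ddof=1)) if len(dens) > 1 else 0.0,
            mean_percent_positive=float(pct.mean()),
            sd_percent_positive=float(pct.std(ddof=1)) if len(pct) > 1 else 0.0,
            histogram=hist,
            dominant_bin_label=hist.bin_label(hist.dominant_bin)
            if hist.n_components
            else "none",
        )
    return report


def iou(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection over union of two same-shape binary masks.

    Defined as 1.0 when both masks are empty.
    """
    ma, mb = a.mask, b.mask
    if ma.shape != mb.shape:
        raise ValidationError(f"shape mismatch {ma.shape} vs {mb.shape}")
    union = int((ma | mb).sum())
    if union == 0:
        return 1.0
    return int((ma & mb).sum()) / union
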