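"""End-to-end orchestration: simulate → weak-label → train → segment → report.

The pipeline mirrors the four-step quantification procedure: (1) a
preliminary thresholding pass produces weak masks per patch, (2) a
consensus selection picks the best candidate per patch (with a hook for
explicit manual corrections), (3) a U-Net is trained on the selected
masks under a slide-level k-fold rotation, and (4) every slide is
segmented by the model that never trained on it, stitched overlap-free,
and quantified into per-organ densities and deposit-size histograms.

All randomness flows from one master seed through named child seeds per
stage, so a config reproduces a run exactly.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .io import BinaryMask, ROIMask, save_image, save_mask
from .quantify import (
    DEFAULT_BIN_EDGES,
    BiodistributionReport,
    build_report,
    components,
    iou,
    quantify_density,
)
from .segmentation import (
    FoldAssignment,
    ModelSpec,
    TrainingSpec,
    filter_components,
    make_folds,
    segment_patches,
    stitch,
    stitch_probabilities,
    train_segmenter,
)
from .synthetic import GroundTruth, OrganPreset, default_organ_presets, make_cohort
from .tiling import TilingSpec, extract_patch, plan_tiles
from .weaklabel import ThresholdParams, select_masks, weak_label

__all__ = ["PipelineConfig", "RunRecord", "SlideResult", "run_pipeline", "load_config"]


def _default_threshold_grid() -> tuple[ThresholdParams, ...]:
    # three parameterizations bracketing the default; consensus selection
    # picks per patch, emulating "best mask" selection across tunings
    return (
        ThresholdParams(),
        ThresholdParams(luminance_percentile=2.0, max_luminance=95.0, min_channel_ratio=1.30),
        ThresholdParams(luminance_percentile=10.0, max_luminance=125.0, min_channel_ratio=1.45),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """One config drives the whole run; desk-scale defaults.

    The synthetic cohort stands in for scanned slides: 7 organ presets ×
    ``slides_per_organ`` replicates at ``slide_dims``/``mpp``.  Tiling,
    threshold grid, model and training specs parameterize the stages.
    """

    slide_dims: tuple[int, int] = (512, 512)
    mpp: float = 0.25
    noise_sd: float = 6.0
    density_scale: float = 1.0  # multiplies every organ preset's density
    slides_per_organ: int = 6
    tiling: TilingSpec = field(
        default_factory=lambda: TilingSpec(patch_size=128, overlap=32)
    )
    threshold_grid: tuple[ThresholdParams, ...] = field(
        default_factory=_default_threshold_grid
    )
    model: ModelSpec = field(default_factory=lambda: ModelSpec(levels=4, base_channels=8))
    training: TrainingSpec = field(
        default_factory=lambda: TrainingSpec(
            epochs=10, batch_size=8, target_train_patches=800, train_patch_edge=64
        )
    )
    k: int = 3
    seed: int = 0
    binarize_threshold: float = 0.5
    # sub-resolution detection filter on stitched probability maps:
    # components < min_component_px are below the smallest reportable
    # deposit area; components < low_confidence_px are kept only if they
    # contain a pixel with probability >= seed_probability
    min_component_px: int = 4
    low_confidence_px: int = 8
    seed_probability: float = 0.65
    # hysteresis delineation: kept detections extend into their connected
    # probability >= extension_threshold halo
    extension_threshold: float = 0.3
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES


@dataclass
class SlideResult:
    """Per-slide artifacts of one pipeline run."""

    slide_id: str
    organ_label: str
    predicted_mask: BinaryMask
    weak_mask: BinaryMask
    truth: GroundTruth | None
    iou_predicted: float | None
    iou_weak: float | None


@dataclass
class RunRecord:
    """Everything a rerun needs plus the computed results."""

    config: PipelineConfig
    folds: FoldAssignment
    slides: dict[str, SlideResult]
    report: BiodistributionReport
    gt_report: BiodistributionReport | None
    component_tables: dict[str, pd.DataFrame]
    stage_seconds: dict[str, float]
    epoch_losses: list[list[float]]
    version: str = ""

    def mean_iou_predicted(self) -> float:
        vals = [s.iou_predicted for s in self.slides.values() if s.iou_predicted is not None]
        return float(np.mean(vals))

    def mean_iou_weak(self) -> float:
        vals = [s.iou_weak for s in self.slides.values() if s.iou_weak is not None]
        return float(np.mean(vals))


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> RunRecord:
    """Execute all stages on a synthetic cohort and build the report.

    When ``out_dir`` is given, per-slide images, masks, component CSVs
    and the per-organ report are written under it.
    """
    from . import __version__

    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    presets = default_organ_presets(
        dims=config.slide_dims, mpp=config.mpp, noise_sd=config.noise_sd
    )
    if config.density_scale != 1.0:
        from dataclasses import replace as _replace

        presets = [
            OrganPreset(
                name=p.name,
                spec=_replace(
                    p.spec, deposit_density=p.spec.deposit_density * config.density_scale
                ),
            )
            for p in presets
        ]
    cohort = make_cohort(presets, config.slides_per_organ, seed=config.seed)
    timings["simulate"] = time.perf_counter() - t0
    if progress:
        print(f"[simulate] {len(cohort)} slides in {timings['simulate']:.1f}s")

    # tile + weak-label + consensus-select, per slide
    t0 = time.perf_counter()
    grids = {}
    patches: dict[str, list[np.ndarray]] = {}
    weak: dict[str, list[np.ndarray]] = {}
    rois: dict[str, ROIMask] = {}
    for image, truth in cohort:
        sid = image.slide_id
        roi = ROIMask(np.ones(image.dims, dtype=bool), source="raster")
        rois[sid] = roi
        grid = plan_tiles(image.dims, roi, config.tiling, slide_id=sid)
        grids[sid] = grid
        pp, ww = [], []
        for i in range(len(grid)):
            patch = extract_patch(image, grid, i)
            cands = [(p, weak_label(patch, p)) for p in config.threshold_grid]
            chosen = select_masks([cands])[0]
            pp.append(patch)
            ww.append(chosen.mask)
        patches[sid] = pp
        weak[sid] = ww
    timings["weak_label"] = time.perf_counter() - t0
    if progress:
        print(f"[weak-label] {timings['weak_label']:.1f}s")

    slide_ids = [img.slide_id for img, _ in cohort]
    folds = make_folds(slide_ids, config.k, seed=config.seed)

    # train one model per rotation, segment its held-out fold only
    t0 = time.perf_counter()
    predicted: dict[str, BinaryMask] = {}
    epoch_losses: list[list[float]] = []
    for rotation in range(config.k):
        train_ids = folds.train_slides(rotation)
        test_ids = folds.test_slides(rotation)
        train_patches = [p for s in train_ids for p in patches[s]]
        train_masks = [m for s in train_ids for m in weak[s]]
        tspec = TrainingSpec(
            epochs=config.training.epochs,
            batch_size=config.training.batch_size,
            learning_rate=config.training.learning_rate,
            seed=config.seed * 1000 + rotation,
            target_train_patches=config.training.target_train_patches,
            train_patch_edge=config.training.train_patch_edge,
            positive_fraction=config.training.positive_fraction,
            pos_weight=config.training.pos_weight,
        )
        seg = train_segmenter(
            train_patches,
            train_masks,
            model_spec=config.model,
            training_spec=tspec,
            train_slide_ids=set(train_ids),
            test_slide_ids=set(test_ids),
            rotation=rotation,
        )
        epoch_losses.append(seg.epoch_losses)
        if progress:
            print(
                f"[train] rotation {rotation}: loss "
                f"{seg.epoch_losses[0]:.4f} -> {seg.epoch_losses[-1]:.4f}"
            )
        for sid in test_ids:
            grid = grids[sid]
            masks = segment_patches(
                patches[sid], seg, slide_id=sid, threshold=config.binarize_threshold
            )
            probs = stitch_probabilities(grid, masks)
            predicted[sid] = filter_components(
                probs,
                threshold=config.binarize_threshold,
                min_px=config.min_component_px,
                low_confidence_px=config.low_confidence_px,
                seed_probability=config.seed_probability,
                extension_threshold=config.extension_threshold,
            )
    timings["train_segment"] = time.perf_counter() - t0
    if progress:
        print(f"[train+segment] {timings['train_segment']:.1f}s")

    # stitch weak masks too (the thresholding-only baseline), then quantify
    t0 = time.perf_counter()
    slides: dict[str, SlideResult] = {}
    stats, tables = [], []
    gt_stats, gt_tables = [], []
    component_tables: dict[str, pd.DataFrame] = {}
    for image, truth in cohort:
        sid = image.slide_id
        grid = grids[sid]
        weak_stitched = stitch(
            grid, [BinaryMask(m, "weak_label") for m in weak[sid]]
        )
        pred = predicted[sid]
        iou_p = iou(pred, truth.mask)
        iou_w = iou(weak_stitched, truth.mask)
        slides[sid] = SlideResult(
            slide_id=sid,
            organ_label=image.organ_label,
            predicted_mask=pred,
            weak_mask=weak_stitched,
            truth=truth,
            iou_predicted=iou_p,
            iou_weak=iou_w,
        )
        table = components(pred, mpp=image.mpp, slide_id=sid)
        component_tables[sid] = table
        tables.append(table)
        stats.append(
            quantify_density(
                pred, rois[sid], image.mpp, organ_label=image.organ_label, slide_id=sid
            )
        )
        gt_tables.append(truth.components)
        gt_stats.append(
            quantify_density(
                truth.mask, rois[sid], image.mpp,
                organ_label=image.organ_label, slide_id=sid,
            )
        )
    report = build_report(stats, tables, config.bin_edges)
    gt_report = build_report(gt_stats, gt_tables, config.bin_edges)
    timings["quantify"] = time.perf_counter() - t0

    record = RunRecord(
        config=config,
        folds=folds,
        slides=slides,
        report=report,
        gt_report=gt_report,
        component_tables=component_tables,
        stage_seconds=timings,
        epoch_losses=epoch_losses,
        version=__version__,
    )
    if out_dir is not None:
        _write_outputs(record, cohort, Path(out_dir))
    return record


def _write_outputs(record: RunRecord, cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(exist_ok=True)
    (out_dir / "images").mkdir(exist_ok=True)
    for image, truth in cohort:
        sid = image.slide_id
        save_image(image, out_dir / "images" / f"{sid}.png")
        save_mask(record.slides[sid].predicted_mask, out_dir / "masks" / f"{sid}_pred.png")
        save_mask(record.slides[sid].weak_mask, out_dir / "masks" / f"{sid}_weak.png")
        save_mask(truth.mask, out_dir / "masks" / f"{sid}_gt.png")
    pd.concat(record.component_tables.values(), ignore_index=True).to_csv(
        out_dir / "components.csv", index=False
    )
    record.report.to_frame().to_csv(out_dir / "report.csv", index=False)
    if record.gt_report is not None:
        record.gt_report.to_frame().to_csv(out_dir / "report_ground_truth.csv", index=False)
    pd.DataFrame(
        [
            {"slide_id": s.slide_id, "fold": record.folds.mapping[s.slide_id],
             "organ": s.organ_label, "iou_predicted": s.iou_predicted,
             "iou_weak": s.iou_weak}
            for s in record.slides.values()
        ]
    ).to_csv(out_dir / "slides.csv", index=False)
    (out_dir / "run.yaml").write_text(yaml.safe_dump(config_to_dict(record.config)))


def config_to_dict(config: PipelineConfig) -> dict[str, Any]:
    d = asdict(config)
    d["threshold_grid"] = [asdict(p) for p in config.threshold_grid]
    d["bin_edges"] = [float(e) if np.isfinite(e) else "inf" for e in config.bin_edges]
    return d


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Build a config from a YAML file plus keyword overrides."""
    data: dict[str, Any] = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    kwargs: dict[str, Any] = {}
    simple = [
        "mpp", "noise_sd", "density_scale", "slides_per_organ", "k", "seed",
        "binarize_threshold", "min_component_px", "low_confidence_px",
        "seed_probability", "extension_threshold",
    ]
    for key in simple:
        if key in data:
            kwargs[key] = data[key]
    if "slide_dims" in data:
        kwargs["slide_dims"] = tuple(data["slide_dims"])
    if "bin_edges" in data:
        kwargs["bin_edges"] = tuple(
            np.inf if e == "inf" else float(e) for e in data["bin_edges"]
        )
    if "tiling" in data:
        t = dict(data["tiling"])
        if "pad_value" in t:
            t["pad_value"] = tuple(t["pad_value"])
        kwargs["tiling"] = TilingSpec(**t)
    if "threshold_grid" in data:
        kwargs["threshold_grid"] = tuple(
            ThresholdParams(**p) for p in data["threshold_grid"]
        )
    if "model" in data:
        kwargs["model"] = ModelSpec(**data["model"])
    if "training" in data:
        kwargs["training"] = TrainingSpec(**data["training"])
    return PipelineConfig(**kwargs)
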