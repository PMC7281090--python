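"""Learned segmentation with slide-level fold rotation and exact stitching.

A small U-Net (:mod:`silverquant.nn`) is trained on weak labels.  Slides
— never patches — are partitioned into *k* folds; per rotation, the
model trains on k−1 folds and segments only the held-out fold, so every
slide is segmented by a model that never saw it.  Patch probability
masks are re-concatenated by center-crop ownership: each section pixel
takes its value from exactly one source patch (the one whose center is
nearest), which removes boundary effects and double counting by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BinaryMask, ValidationError
from .nn import Adam, UNet, bce_with_logits, bce_with_logits_grad
from .tiling import PatchGrid

__all__ = [
    "ModelSpec",
    "TrainingSpec",
    "FoldAssignment",
    "FoldLeakError",
    "ProbabilityMask",
    "Segmenter",
    "make_folds",
    "make_training_set",
    "train_segmenter",
    "segment_patch",
    "segment_patches",
    "stitch",
    "stitch_probabilities",
    "filter_components",
]


class FoldLeakError(RuntimeError):
    """Attempt to segment a slide that was in the model's training folds."""


@dataclass(frozen=True)
class ModelSpec:
    """U-Net shape: encoder depth and first-level channel count.

    Channels double per level, so the deepest (bottleneck) count is
    ``base_channels * 2**levels`` — 256 with the defaults.
    """

    levels: int = 4
    base_channels: int = 16

    def __post_init__(self) -> None:
        if self.levels < 1 or self.base_channels < 1:
            raise ValidationError("levels and base_channels must be >= 1")

    @property
    def encoder_channels(self) -> list[int]:
        return [self.base_channels * 2**l for l in range(self.levels + 1)]


@dataclass(frozen=True)
class TrainingSpec:
    """Optimization recipe.

    ``target_train_patches`` is the approximate training-set size; when
    the cohort yields fewer tiles, flip/rotation augmentation tops the
    set up, and when it yields more, a deterministic subsample is used.
    ``positive_fraction`` stratifies that subsample toward tiles that
    contain any weak-positive pixels, so sparse cohorts still expose the
    model to enough deposit boundaries.  ``pos_weight`` optionally scales
    positive-pixel loss (1.0 = plain pixelwise binary cross-entropy).
    """

    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 2e-3
    seed: int = 0
    target_train_patches: int = 5000
    train_patch_edge: int = 256
    positive_fraction: float = 0.6
    pos_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 1 or self.target_train_patches < 1:
            raise ValidationError("batch_size and target_train_patches must be >= 1")


@dataclass
class FoldAssignment:
    """Slide-level k-fold partition with per-rotation train/test lists."""

    k: int
    mapping: dict[str, int]

    def test_slides(self, rotation: int) -> list[str]:
        return sorted(s for s, f in self.mapping.items() if f == rotation)

    def train_slides(self, rotation: int) -> list[str]:
        return sorted(s for s, f in self.mapping.items() if f != rotation)


def make_folds(slide_ids: list[str], k: int, seed: int) -> FoldAssignment:
    """Deterministic near-equal slide-level folds (sizes differ by ≤ 1)."""
    ids = list(slide_ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("slide_ids must be unique")
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(ids):
        raise ValidationError(f"k={k} exceeds slide count {len(ids)}")
    rng = np.random.default_rng(seed)
    order = list(np.array(sorted(ids))[rng.permutation(len(ids))])
    mapping = {s: i % k for i, s in enumerate(order)}
    return FoldAssignment(k=k, mapping=mapping)


@dataclass
class ProbabilityMask:
    """Per-pixel AuNP probability grid in [0, 1]."""

    probs: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValidationError("probabilities must lie in [0, 1]")

    def binarize(self) -> BinaryMask:
        return BinaryMask(self.probs >= self.threshold, provenance="predicted")


@dataclass
class Segmenter:
    """Trained model handle bound to its fold rotation."""

    net: UNet
    train_slide_ids: frozenset[str]
    test_slide_ids: frozenset[str]
    rotation: int = 0
    epoch_losses: list[float] = field(default_factory=list)


def _augment(patch: np.ndarray, mask: np.ndarray, code: int):
    """One of 8 dihedral transforms (flips/rot90), same for patch and mask."""
    if code & 1:
        patch, mask = patch[::-1], mask[::-1]
    if code & 2:
        patch, mask = patch[:, ::-1], mask[:, ::-1]
    if code & 4:
        patch = np.rot90(patch, axes=(0, 1))
        mask = np.rot90(mask, axes=(0, 1))
    return np.ascontiguousarray(patch), np.ascontiguousarray(mask)


def make_training_set(
    patches: list[np.ndarray],
    masks: list[np.ndarray],
    edge: int,
    target: int,
    seed: int,
    positive_fraction: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut patches into ``edge×edge`` tiles and size the set to ``target``.

    Tiles are taken on a non-overlapping grid; if more than ``target``
    exist a deterministic subsample is drawn — stratified so that about
    ``positive_fraction`` of it comes from tiles containing weak-positive
    pixels (when available) — otherwise repeats top the set up.  Every
    selected tile receives a random dihedral transform (flip/rot90
    augmentation).  Returns ``(X, Y)`` with ``X`` of shape
    (N, edge, edge, 3) float32 in [0, 1] and ``Y`` binary.
    """
    if len(patches) != len(masks) or not patches:
        raise ValidationError("need equal, non-empty patch and mask lists")
    tiles_x, tiles_y = [], []
    for p, m in zip(patches, masks):
        if p.shape[:2] != m.shape:
            raise ValidationError("patch/mask shape mismatch")
        h, w = m.shape
        for r in range(0, h - edge + 1, edge):
            for c in range(0, w - edge + 1, edge):
                tiles_x.append(p[r : r + edge, c : c + edge])
                tiles_y.append(m[r : r + edge, c : c + edge])
    if not tiles_x:
        raise ValidationError(f"patches smaller than training edge {edge}")
    rng = np.random.default_rng(seed)
    n = len(tiles_x)
    if n >= target:
        has_pos = np.array([m.any() for m in tiles_y])
        pos_idx = np.flatnonzero(has_pos)
        neg_idx = np.flatnonzero(~has_pos)
        n_pos = min(len(pos_idx), int(round(target * positive_fraction)))
        n_neg = target - n_pos
        if n_neg > len(neg_idx):  # not enough background tiles: take more positive
            n_pos = min(len(pos_idx), target - len(neg_idx))
            n_neg = target - n_pos
        keep = np.concatenate(
            [
                rng.choice(pos_idx, size=n_pos, replace=False)
                if n_pos
                else np.empty(0, int),
                rng.choice(neg_idx, size=n_neg, replace=False)
                if n_neg
                else np.empty(0, int),
            ]
        )
    else:
        keep = np.concatenate([np.arange(n), rng.integers(0, n, target - n)])
    codes = rng.integers(0, 8, size=len(keep))
    chosen = [(tiles_x[i], tiles_y[i], int(c)) for i, c in zip(keep, codes)]
    X = np.empty((len(chosen), edge, edge, 3), dtype=np.float32)
    Y = np.empty((len(chosen), edge, edge), dtype=np.float32)
    for i, (x, y, code) in enumerate(chosen):
        x, y = _augment(x, y, code)
        X[i] = x.astype(np.float32) / 255.0
        Y[i] = y.astype(np.float32)
    return X, Y


def train_segmenter(
    train_patches: list[np.ndarray],
    weak_masks: list[np.ndarray],
    model_spec: ModelSpec = ModelSpec(),
    training_spec: TrainingSpec = TrainingSpec(),
    train_slide_ids: set[str] | None = None,
    test_slide_ids: set[str] | None = None,
    rotation: int = 0,
) -> Segmenter:
    """Train the U-Net on weak-labeled patches of the training folds.

    Per-epoch mean loss is recorded on the returned handle; with a fixed
    seed the trajectory is reproducible up to floating-point accumulation
    order.
    """
    X, Y = make_training_set(
        train_patches,
        weak_masks,
        edge=training_spec.train_patch_edge,
        target=training_spec.target_train_patches,
        seed=training_spec.seed,
        positive_fraction=training_spec.positive_fraction,
    )
    net = UNet(
        levels=model_spec.levels,
        base_channels=model_spec.base_channels,
        seed=training_spec.seed,
    )
    opt = Adam(net, lr=training_spec.learning_rate)
    rng = np.random.default_rng(training_spec.seed + 1)
    n = len(X)
    bs = training_spec.batch_size
    losses = []
    for _epoch in range(training_spec.epochs):
        # half-cosine learning-rate decay over the epoch budget
        opt.lr = training_spec.learning_rate * 0.5 * (
            1.0 + np.cos(np.pi * _epoch / training_spec.epochs)
        )
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = X[idx], Y[idx]
            z = net.forward(xb)
            epoch_loss += bce_with_logits(z, yb, training_spec.pos_weight)
            net.backward(bce_with_logits_grad(z, yb, training_spec.pos_weight))
            opt.step()
            nb += 1
        losses.append(epoch_loss / max(nb, 1))
    return Segmenter(
        net=net,
        train_slide_ids=frozenset(train_slide_ids or set()),
        test_slide_ids=frozenset(test_slide_ids or set()),
        rotation=rotation,
        epoch_losses=losses,
    )


def segment_patch(
    patch: np.ndarray,
    segmenter: Segmenter,
    slide_id: str | None = None,
    allow_train_slides: bool = False,
    threshold: float = 0.5,
) -> ProbabilityMask:
    """Per-pixel AuNP probabilities for one RGB patch.

    Refuses patches from the segmenter's own training folds unless
    ``allow_train_slides`` is set (debugging escape hatch).  Patch edges
    not divisible by the model's pooling factor are reflect-padded and
    the output cropped back.
    """
    if (
        slide_id is not None
        and slide_id in segmenter.train_slide_ids
        and not allow_train_slides
    ):
        raise FoldLeakError(
            f"slide {slide_id!r} is in the training folds of rotation "
            f"{segmenter.rotation}; pass allow_train_slides=True to override"
        )
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValidationError("patch must be H×W×3")
    h, w = patch.shape[:2]
    d = 2**segmenter.net.levels
    ph = (d - h % d) % d
    pw = (d - w % d) % d
    x = patch.astype(np.float32) / 255.0
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    probs = segmenter.net.predict(x[None])[0, :h, :w]
    return ProbabilityMask(np.clip(probs, 0.0, 1.0), threshold=threshold)


def segment_patches(
    patches: list[np.ndarray],
    segmenter: Segmenter,
    slide_id: str | None = None,
    allow_train_slides: bool = False,
    threshold: float = 0.5,
    batch_size: int = 8,
) -> list[ProbabilityMask]:
    """Batched :func:`segment_patch` over same-shape patches of one slide."""
    if not patches:
        return []
    if (
        slide_id is not None
        and slide_id in segmenter.train_slide_ids
        and not allow_train_slides
    ):
        raise FoldLeakError(
            f"slide {slide_id!r} is in the training folds of rotation "
            f"{segmenter.rotation}; pass allow_train_slides=True to override"
        )
    h, w = patches[0].shape[:2]
    d = 2**segmenter.net.levels
    ph, pw = (d - h % d) % d, (d - w % d) % d
    out: list[ProbabilityMask] = []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start : start + batch_size]
        x = np.stack(chunk).astype(np.float32) / 255.0
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="reflect")
        probs = segmenter.net.predict(x)[:, :h, :w]
        out.extend(
            ProbabilityMask(np.clip(p, 0.0, 1.0), threshold=threshold) for p in probs
        )
    return out


def filter_components(
    probs: np.ndarray,
    threshold: float = 0.5,
    min_px: int = 4,
    low_confidence_px: int = 8,
    seed_probability: float = 0.65,
    extension_threshold: float = 0.3,
) -> BinaryMask:
    """Binarize a stitched probability map with filtering and hysteresis.

    Detection: connected regions of ``probs >= threshold``.  Components
    below ``min_px`` pixels are speckle by definition (below the
    smallest reportable deposit area); components below
    ``low_confidence_px`` must additionally contain at least one pixel
    with probability >= ``seed_probability`` — small detections without a
    confident core are noise, while every real deposit the model finds
    has one.  Larger components are kept regardless.

    Delineation: every kept detection is then extended into its
    connected ``probs >= extension_threshold`` halo (Canny-style
    hysteresis), which corrects the systematic boundary erosion of a
    hard cut on soft probability edges.  Set ``extension_threshold >=
    threshold`` to disable the extension.
    """
    from scipy import ndimage

    struct = np.ones((3, 3), bool)
    mask = probs >= threshold
    if not mask.any():
        return BinaryMask(mask, provenance="predicted")
    labels, n = ndimage.label(mask, structure=struct)
    sizes = np.bincount(labels.ravel())
    maxp = ndimage.labeled_comprehension(
        probs, labels, np.arange(1, n + 1), np.max, float, 0.0
    )
    keep = np.zeros(n + 1, dtype=bool)
    for i in range(1, n + 1):
        sz = sizes[i]
        if sz < min_px:
            continue
        if sz < low_confidence_px and maxp[i - 1] < seed_probability:
            continue
        keep[i] = True
    seeds = keep[labels]
    if extension_threshold >= threshold or not seeds.any():
        return BinaryMask(seeds, provenance="predicted")
    low_labels, _ = ndimage.label(probs >= extension_threshold, structure=struct)
    keep_low = np.unique(low_labels[seeds])
    keep_low = keep_low[keep_low > 0]
    return BinaryMask(np.isin(low_labels, keep_low), provenance="predicted")


def _axis_owner(anchors: list[int], patch: int, dim: int) -> np.ndarray:
    """For each coordinate, the index of the nearest-center anchor.

    Ties go to the earlier anchor (row-major precedence).
    """
    centers = np.asarray(anchors, dtype=np.float64) + patch / 2.0
    coords = np.arange(dim) + 0.5
    dist = np.abs(coords[:, None] - centers[None, :])
    return dist.argmin(axis=1)  # argmin is stable -> earlier anchor wins ties


def _stitch_field(
    grid: PatchGrid, fields: dict[tuple[int, int], np.ndarray], dtype
) -> np.ndarray:
    """Center-crop-ownership stitching of per-anchor 2-D fields."""
    p = grid.patch_size
    ph, pw = grid.padded_dims
    row_anchors = sorted({a for a, _ in grid.anchors})
    col_anchors = sorted({c for _, c in grid.anchors})
    row_owner = _axis_owner(row_anchors, p, ph)
    col_owner = _axis_owner(col_anchors, p, pw)
    out = np.zeros((ph, pw), dtype=dtype)
    for ri, ar in enumerate(row_anchors):
        rows = np.nonzero(row_owner == ri)[0]
        r0, r1 = rows[0], rows[-1] + 1
        for ci, ac in enumerate(col_anchors):
            if (ar, ac) not in fields:
                # anchor omitted by ROI pruning: that region stays background
                continue
            cols = np.nonzero(col_owner == ci)[0]
            c0, c1 = cols[0], cols[-1] + 1
            out[r0:r1, c0:c1] = fields[(ar, ac)][r0 - ar : r1 - ar, c0 - ac : c1 - ac]
    h, w = grid.image_dims
    return out[:h, :w]


def _check_patch_masks(grid: PatchGrid, patch_masks) -> None:
    if len(patch_masks) != len(grid.anchors):
        missing = len(grid.anchors) - len(patch_masks)
        raise ValidationError(
            f"need one mask per anchor: {len(grid.anchors)} anchors, "
            f"{len(patch_masks)} masks ({missing} missing)"
        )
    p = grid.patch_size
    for anchor, pm in zip(grid.anchors, patch_masks):
        arr = pm.probs if isinstance(pm, ProbabilityMask) else pm.mask
        if arr.shape != (p, p):
            raise ValidationError(
                f"patch mask shape {arr.shape} != ({p}, {p}) at anchor {anchor}"
            )


def stitch_probabilities(
    grid: PatchGrid, patch_masks: list[ProbabilityMask]
) -> np.ndarray:
    """Stitch patch probability fields into one section-sized float map.

    Same center-crop ownership as :func:`stitch`; binary masks passed in
    are treated as 0/1 probabilities.
    """
    _check_patch_masks(grid, patch_masks)
    fields = {
        anchor: (
            pm.probs
            if isinstance(pm, ProbabilityMask)
            else pm.mask.astype(np.float32)
        )
        for anchor, pm in zip(grid.anchors, patch_masks)
    }
    return _stitch_field(grid, fields, np.float32)


def stitch(
    grid: PatchGrid,
    patch_masks: list[ProbabilityMask | BinaryMask],
    threshold: float = 0.5,
) -> BinaryMask:
    """Re-concatenate patch masks into one section mask, overlap-free.

    Each padded-grid pixel takes its value from exactly one source patch
    — the patch whose center is nearest along each axis (ties to the
    earlier anchor) — so overlapping margins are center-cropped and
    nothing is counted twice.  The result is cropped to the original
    image dims and binarized at ``threshold``.
    """
    _check_patch_masks(grid, patch_masks)
    fields = {
        anchor: (pm.probs >= threshold if isinstance(pm, ProbabilityMask) else pm.mask)
        for anchor, pm in zip(grid.anchors, patch_masks)
    }
    return BinaryMask(_stitch_field(grid, fields, bool), provenance="predicted")
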