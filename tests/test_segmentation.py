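import numpy as np
import pytest

from silverquant.io import BinaryMask, ROIMask, ValidationError
from silverquant.quantify import components, iou
from silverquant.segmentation import (
    FoldLeakError,
    ModelSpec,
    ProbabilityMask,
    TrainingSpec,
    filter_components,
    make_folds,
    make_training_set,
    segment_patch,
    stitch,
    stitch_probabilities,
    train_segmenter,
)
from silverquant.tiling import TilingSpec, plan_tiles


def full_roi(dims):
    return ROIMask(np.ones(dims, dtype=bool))


class TestMakeFolds:
    def test_42_slides_k3_gives_28_train_14_test(self):
        ids = [f"s{i:02d}" for i in range(42)]
        folds = make_folds(ids, k=3, seed=0)
        for r in range(3):
            assert len(folds.train_slides(r)) == 28
            assert len(folds.test_slides(r)) == 14

    def test_leave_one_out_limit(self):
        folds = make_folds(["a", "b", "c", "d"], k=4, seed=1)
        assert all(len(folds.test_slides(r)) == 1 for r in range(4))

    @pytest.mark.parametrize("n,k,seed", [(10, 3, 0), (11, 4, 7), (42, 3, 5)])
    def test_partition_property(self, n, k, seed):
        ids = [f"s{i}" for i in range(n)]
        folds = make_folds(ids, k, seed)
        all_test = [s for r in range(k) for s in folds.test_slides(r)]
        assert sorted(all_test) == sorted(ids)  # disjoint and exhaustive
        for r in range(k):
            assert not set(folds.test_slides(r)) & set(folds.train_slides(r))
        sizes = [len(folds.test_slides(r)) for r in range(k)]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_given_seed(self):
        ids = [f"s{i}" for i in range(9)]
        assert make_folds(ids, 3, 42).mapping == make_folds(ids, 3, 42).mapping

    def test_k_validation(self):
        with pytest.raises(ValidationError):
            make_folds(["a", "b"], k=3, seed=0)
        with pytest.raises(ValidationError):
            make_folds(["a", "b", "c"], k=1, seed=0)


class TestStitch:
    def _grid(self, dims, patch, overlap):
        return plan_tiles(dims, full_roi(dims), TilingSpec(patch, overlap))

    def test_single_patch_identity(self, rng):
        grid = self._grid((64, 64), 64, 8)
        m = rng.random((64, 64)) > 0.5
        out = stitch(grid, [BinaryMask(m)])
        assert np.array_equal(out.mask, m)

    def test_reconstruction_identity_on_random_masks(self, rng):
        """stitch(crops of M) == M bit-exactly for 50 random geometries."""
        for _ in range(50):
            h, w = (int(x) for x in rng.integers(40, 300, 2))
            patch = int(rng.integers(16, 150))
            overlap = int(rng.integers(1, patch))
            grid = self._grid((h, w), patch, overlap)
            m = rng.random((h, w)) > 0.5
            mp = np.zeros(grid.padded_dims, dtype=bool)
            mp[:h, :w] = m
            crops = [
                BinaryMask(mp[r : r + patch, c : c + patch])
                for r, c in grid.anchors
            ]
            out = stitch(grid, crops)
            assert np.array_equal(out.mask, m)

    def test_component_in_overlap_zone_counted_once(self, rng):
        """A deposit wholly inside an overlap margin appears exactly once:
        stitched component count equals whole-image count."""
        h = w = 220
        grid = self._grid((h, w), 128, 36)
        m = np.zeros((h, w), dtype=bool)
        # deposit centered on the overlap band between column anchors 0 and 92
        m[60:70, 95:120] = True
        m[130:140, 10:20] = True
        crops = [
            BinaryMask(m[r : r + 128, c : c + 128]) for r, c in grid.anchors
        ]
        out = stitch(grid, crops)
        assert np.array_equal(out.mask, m)
        assert len(components(out, 1.0)) == len(components(BinaryMask(m), 1.0)) == 2

    def test_missing_masks_rejected_with_count(self):
        grid = self._grid((200, 200), 128, 36)
        with pytest.raises(ValidationError, match="missing"):
            stitch(grid, [BinaryMask(np.zeros((128, 128), bool))])

    def test_probability_masks_binarized_at_threshold(self):
        grid = self._grid((64, 64), 64, 8)
        pm = ProbabilityMask(np.full((64, 64), 0.6, np.float32))
        assert stitch(grid, [pm], threshold=0.5).mask.all()
        assert not stitch(grid, [pm], threshold=0.7).mask.any()

    def test_probability_field_stitches_like_mask(self, rng):
        grid = self._grid((150, 150), 96, 24)
        pms = [
            ProbabilityMask(rng.random((96, 96)).astype(np.float32))
            for _ in grid.anchors
        ]
        probs = stitch_probabilities(grid, pms)
        assert probs.shape == (150, 150)
        assert np.array_equal(probs >= 0.5, stitch(grid, pms).mask)


class TestFilterComponents:
    def _field(self):
        p = np.zeros((32, 32), np.float32)
        return p

    def test_sub_resolution_specks_removed(self):
        p = self._field()
        p[2, 2:4] = 0.9  # 2 px, below the 4 px floor despite confidence
        assert not filter_components(p).mask.any()

    def test_small_component_needs_confident_core(self):
        p = self._field()
        p[5:7, 5:8] = 0.55  # 6 px, peak 0.55 < 0.65 -> dropped
        p[20:22, 20:23] = 0.55
        p[20, 20] = 0.8  # 6 px with a confident pixel -> kept, full extent
        out = filter_components(p).mask
        assert not out[5:7, 5:8].any()
        assert out[20:22, 20:23].all()

    def test_large_components_kept_regardless_of_confidence(self):
        p = self._field()
        p[10:14, 10:14] = 0.55  # 16 px at low confidence
        assert filter_components(p).mask.sum() == 16

    def test_hysteresis_extends_kept_detections_only(self):
        p = self._field()
        p[10:14, 10:14] = 0.9  # confident detection
        p[10:14, 14:17] = 0.4  # soft halo attached to it -> included
        p[25:28, 25:28] = 0.4  # soft region with no seed -> excluded
        out = filter_components(p).mask
        assert out[10:14, 10:17].all()
        assert not out[25:28, 25:28].any()
        # disabling the extension keeps only the hard-threshold extent
        hard = filter_components(p, extension_threshold=0.5).mask
        assert hard[10:14, 10:14].all() and not hard[10:14, 14:17].any()

    def test_empty_field_stays_empty(self):
        assert not filter_components(self._field()).mask.any()


def _toy_patches(rng, n=6, edge=32):
    """Trivially separable synthetic task: dark blobs on bright ground."""
    patches, masks = [], []
    for _ in range(n):
        img = np.full((edge, edge, 3), 220, np.uint8)
        m = np.zeros((edge, edge), dtype=bool)
        r, c = rng.integers(4, edge - 12, 2)
        img[r : r + 8, c : c + 8] = 25
        m[r : r + 8, c : c + 8] = True
        patches.append(img)
        masks.append(m)
    return patches, masks


class TestTrainSegmenter:
    def test_loss_decreases_on_separable_task(self, rng):
        patches, masks = _toy_patches(rng, n=8)
        spec = TrainingSpec(epochs=4, batch_size=4, target_train_patches=32,
                            train_patch_edge=16, seed=0)
        seg = train_segmenter(patches, masks, ModelSpec(levels=2, base_channels=4),
                              spec, {"a"}, {"b"})
        assert seg.epoch_losses[-1] < seg.epoch_losses[0]
        assert len(seg.epoch_losses) == 4

    def test_fold_leak_guard(self, rng):
        patches, masks = _toy_patches(rng, n=4)
        spec = TrainingSpec(epochs=1, batch_size=4, target_train_patches=8,
                            train_patch_edge=16, seed=0)
        seg = train_segmenter(patches, masks, ModelSpec(levels=2, base_channels=4),
                              spec, {"train_slide"}, {"test_slide"})
        patch = patches[0]
        with pytest.raises(FoldLeakError):
            segment_patch(patch, seg, slide_id="train_slide")
        # override and held-out slide both allowed
        segment_patch(patch, seg, slide_id="train_slide", allow_train_slides=True)
        out = segment_patch(patch, seg, slide_id="test_slide")
        assert out.probs.shape == patch.shape[:2]

    def test_inference_deterministic(self, rng):
        patches, masks = _toy_patches(rng, n=4)
        spec = TrainingSpec(epochs=1, batch_size=4, target_train_patches=8,
                            train_patch_edge=16, seed=0)
        seg = train_segmenter(patches, masks, ModelSpec(levels=2, base_channels=4),
                              spec, set(), set())
        a = segment_patch(patches[0], seg)
        b = segment_patch(patches[0], seg)
        assert np.array_equal(a.probs, b.probs)

    def test_shape_mismatch_rejected(self, rng):
        patches, masks = _toy_patches(rng, n=2)
        masks[0] = masks[0][:-4]
        with pytest.raises(ValidationError):
            make_training_set(patches, masks, edge=16, target=8, seed=0)

    def test_training_set_sizing_and_range(self, rng):
        patches, masks = _toy_patches(rng, n=3, edge=32)
        X, Y = make_training_set(patches, masks, edge=16, target=20, seed=0)
        assert X.shape == (20, 16, 16, 3) and Y.shape == (20, 16, 16)
        assert 0.0 <= X.min() and X.max() <= 1.0
        assert set(np.unique(Y)) <= {0.0, 1.0}
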