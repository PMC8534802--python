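"""Region growing, hole filling, image quality and mask comparison."""

import numpy as np
import pytest

from aortoflow.imaging import (
    ImageVolume,
    RoiSpec,
    SegmentationMask,
    compare_masks,
    fill_holes,
    image_quality,
    region_grow,
    robust_seed_point,
    window_level,
)
from aortoflow.pipeline import default_tolerance
from aortoflow.synthetic import PhantomSpec, generate_phantom

SP = (1.0, 1.0, 1.0)


class TestRegionGrow:
    def test_center_plus_six_neighbours(self):
        """Exhaustive hand flood-fill on a 3x3x3 plus-shaped object."""
        vox = np.full((3, 3, 3), 50.0)
        vox[1, 1, 1] = 200.0
        for d in ((0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)):
            vox[d] = 200.0
        mask = region_grow(ImageVolume(vox, SP), (1, 1, 1), tolerance=30.0)
        assert int(mask.voxels.sum()) == 7
        assert mask.voxels[1, 1, 1]

    def test_zero_tolerance_on_noiseless_phantom(self):
        spec = PhantomSpec(noise_sd=0.0, seed=0)
        vol, truth = generate_phantom(spec)
        seed = robust_seed_point(vol)
        mask = region_grow(vol, seed, tolerance=0.0)
        assert np.array_equal(mask.voxels, truth.voxels)

    def test_noisy_phantom_volume_within_five_percent(self):
        spec = PhantomSpec(
            object_intensity=100.0, background_intensity=50.0, noise_sd=4.0, seed=4
        )
        vol, truth = generate_phantom(spec)
        mask = fill_holes(region_grow(vol, robust_seed_point(vol), tolerance=25.0))
        err, dice = compare_masks(mask, truth)
        assert err <= 5.0
        assert dice > 0.95

    def test_output_connected_and_contains_seed(self):
        from scipy import ndimage

        vol, _ = generate_phantom(PhantomSpec(seed=9))
        seed = robust_seed_point(vol)
        mask = region_grow(vol, seed, default_tolerance(PhantomSpec(seed=9)))
        assert mask.voxels[seed]
        labels, n = ndimage.label(
            mask.voxels, structure=ndimage.generate_binary_structure(3, 1)
        )
        assert n == 1

    def test_seed_outside_grid_raises(self):
        vol = ImageVolume(np.zeros((4, 4, 4)), SP)
        with pytest.raises(IndexError):
            region_grow(vol, (5, 0, 0), 1.0)

    def test_negative_tolerance_raises(self):
        vol = ImageVolume(np.zeros((4, 4, 4)), SP)
        with pytest.raises(ValueError):
            region_grow(vol, (1, 1, 1), -1.0)


class TestFillHoles:
    def test_textbook_ring_hole(self):
        sl = np.zeros((5, 5, 1), bool)
        sl[1:4, 1:4, 0] = True
        sl[2, 2, 0] = False
        out = fill_holes(SegmentationMask(sl, SP))
        assert out.voxels[2, 2, 0]
        assert out.voxels.sum() == sl.sum() + 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = SegmentationMask(rng.random((12, 12, 4)) > 0.5, SP)
        once = fill_holes(m)
        twice = fill_holes(once)
        assert np.array_equal(once.voxels, twice.voxels)
        assert np.all(once.voxels >= m.voxels)  # superset of input

    def test_border_channel_stays_open(self):
        """4-connectivity audit on a 7x7 slice: a channel reaching the
        border is background, not a hole."""
        sl = np.zeros((7, 7, 1), bool)
        sl[1:6, 1:6, 0] = True
        sl[2:5, 3, 0] = False  # cavity ...
        sl[0:3, 3, 0] = False  # ... connected to the border
        out = fill_holes(SegmentationMask(sl, SP))
        assert not out.voxels[2, 3, 0]
        assert np.array_equal(out.voxels[:, :, 0], sl[:, :, 0])


class TestImageQuality:
    def _volume_with_rois(self, obj=100.0, bg=80.0, bg_noise=4.0, seed=0):
        rng = np.random.default_rng(seed)
        vox = np.full((40, 40, 5), bg)
        vox += rng.normal(0.0, bg_noise, vox.shape)
        vox[15:25, 15:25, :] += obj - bg
        return ImageVolume(vox, SP)

    def test_matches_direct_roi_statistics(self):
        vol = self._volume_with_rois()
        obj = RoiSpec((20.0, 20.0), 64.0)
        left = RoiSpec((5.0, 20.0), 36.0)
        right = RoiSpec((35.0, 20.0), 36.0)
        rep = image_quality(vol, obj, (left, right))
        # independent oracle: direct numpy statistics on the same ROIs
        noise, bis, cnrs = [], [], []
        for k in range(5):
            patches = [
                vol.voxels[r.slices(SP)[0], r.slices(SP)[1], k] for r in (left, right)
            ]
            nz = np.mean([p.std(ddof=1) for p in patches])
            om = vol.voxels[obj.slices(SP)[0], obj.slices(SP)[1], k].mean()
            bm = np.mean([p.mean() for p in patches])
            noise.append(nz)
            bis.append(om)
            cnrs.append((om, bm))
        exp_noise = float(np.mean(noise))
        exp_obj = float(np.mean([b for b in bis]))
        exp_bg = float(np.mean([b for _, b in cnrs]))
        assert rep.noise == pytest.approx(exp_noise, rel=1e-12)
        assert rep.bi == pytest.approx(exp_obj / exp_noise, rel=1e-12)
        assert rep.cnr == pytest.approx((exp_obj - exp_bg) / exp_noise, rel=1e-12)

    def test_zero_contrast_gives_zero_cnr(self):
        vol = self._volume_with_rois(obj=80.0, bg=80.0, bg_noise=4.0)
        rep = image_quality(
            vol,
            RoiSpec((20.0, 20.0), 64.0),
            (RoiSpec((5.0, 20.0), 36.0), RoiSpec((35.0, 20.0), 36.0)),
        )
        assert rep.cnr == pytest.approx(0.0, abs=0.2)

    def test_zero_noise_flagged_undefined(self):
        vol = ImageVolume(np.full((30, 30, 2), 90.0), SP)
        rep = image_quality(
            vol,
            RoiSpec((15.0, 15.0), 25.0),
            (RoiSpec((4.0, 15.0), 16.0), RoiSpec((26.0, 15.0), 16.0)),
        )
        assert rep.undefined
        assert np.isnan(rep.bi) and np.isnan(rep.cnr)

    def test_roi_outside_grid_rejected(self):
        vol = ImageVolume(np.zeros((10, 10, 2)), SP)
        with pytest.raises(ValueError):
            image_quality(
                vol,
                RoiSpec((5.0, 5.0), 9.0),
                (RoiSpec((-3.0, 5.0), 9.0), RoiSpec((9.0, 5.0), 9.0)),
            )

    def test_window_level_is_linear_and_clipped(self):
        vol = ImageVolume(np.array([[[0.0, 50.0, 100.0, 150.0]]]), SP)
        out = window_level(vol, window=100.0, level=100.0)
        assert out.voxels[0, 0, 0] == 0.0
        assert out.voxels[0, 0, 1] == 0.0
        assert out.voxels[0, 0, 2] == 127.5
        assert out.voxels[0, 0, 3] == 255.0


class TestCompareMasks:
    def test_identity(self):
        m = SegmentationMask(np.ones((3, 3, 3), bool), SP)
        err, dice = compare_masks(m, m)
        assert err == 0.0 and dice == 1.0

    def test_one_missing_of_twenty(self):
        truth = np.zeros((5, 5, 5), bool)
        truth.flat[:20] = True
        est = truth.copy()
        est.flat[0] = False
        err, dice = compare_masks(
            SegmentationMask(est, SP), SegmentationMask(truth, SP)
        )
        assert err == pytest.approx(5.0)
        assert dice == pytest.approx(38.0 / 39.0)

    def test_disjoint_equal_sizes(self):
        """Volume error alone is blind to displacement; Dice is not."""
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a.flat[:8] = True
        b.flat[8:16] = True
        err, dice = compare_masks(SegmentationMask(a, SP), SegmentationMask(b, SP))
        assert err == 0.0 and dice == 0.0

    def test_empty_truth_rejected(self):
        a = SegmentationMask(np.ones((2, 2, 2), bool), SP)
        empty = SegmentationMask(np.zeros((2, 2, 2), bool), SP)
        with pytest.raises(ValueError):
            compare_masks(a, empty)
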