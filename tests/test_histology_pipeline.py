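"""Histology image processing: segmentation, registration, density maps."""

import numpy as np
import pytest
from scipy import ndimage

from tumorhab.histology import (density_at, density_map, downsample_density,
                                label_habitats_histology, rigid_register,
                                segment_dab, segment_hne, stack_from_masks,
                                tissue_mask)
from tumorhab.synth.histology import (COLOR_BACKGROUND, COLOR_EOSIN,
                                      COLOR_NUCLEUS)


class TestSegmentHne:
    def _disc_image(self, rng):
        img = np.broadcast_to(COLOR_BACKGROUND, (200, 200, 3)).copy()
        truth = np.zeros((200, 200), dtype=bool)
        yy, xx = np.mgrid[:200, :200]
        img[40:160, 40:160] = COLOR_EOSIN
        for cy, cx in rng.integers(55, 145, size=(15, 2)):
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= 36
            img[disc] = COLOR_NUCLEUS
            truth |= disc
        img = np.clip(img + rng.normal(0, 2, img.shape), 0, 255)
        return img.astype(np.uint8), truth

    def test_nuclei_dice_against_generator_truth(self, rng):
        img, truth = self._disc_image(rng)
        nuclei, _ = segment_hne(img, seed=0)
        inter = (nuclei & truth).sum()
        dice = 2 * inter / (nuclei.sum() + truth.sum())
        assert dice >= 0.95

    def test_blank_image_empty_masks(self):
        img = np.full((50, 50, 3), 255, dtype=np.uint8)
        nuclei, necrosis = segment_hne(img)
        assert not nuclei.any() and not necrosis.any()

    def test_same_seed_identical(self, rng):
        img, _ = self._disc_image(rng)
        a, _ = segment_hne(img, seed=1)
        b, _ = segment_hne(img, seed=1)
        np.testing.assert_array_equal(a, b)


def brute_force_otsu(img):
    """Exhaustive 256-level between-class variance maximization."""
    lo, hi = img.min(), img.max()
    edges = np.linspace(lo, hi, 257)
    hist, _ = np.histogram(img, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_v = None, -1
    for i in range(1, 256):
        w0, w1 = hist[:i].sum(), hist[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:i] * centers[:i]).sum() / w0
        m1 = (hist[i:] * centers[i:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_t, best_v = centers[i - 1], v
    return best_t


class TestSegmentDab:
    def test_two_level_image_threshold_between_levels(self):
        img = np.full((20, 20), 50.0)
        img[:, 10:] = 200.0
        mask = segment_dab(img)
        assert mask.sum() == 200
        assert mask[:, 10:].all()

    def test_constant_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            mask = segment_dab(np.full((10, 10), 7.0))
        assert not mask.any()

    def test_bimodal_matches_brute_force_otsu(self, rng):
        img = np.concatenate([rng.normal(60, 10, 5000),
                              rng.normal(180, 15, 5000)]).reshape(100, 100)
        mask = segment_dab(img)
        oracle = img > brute_force_otsu(img)
        assert (mask == oracle).mean() > 0.999


class TestTissueMask:
    def _blob_image(self):
        img = np.full((120, 120, 3), 245.0)
        yy, xx = np.mgrid[:120, :120]
        blob = (yy - 60) ** 2 + (xx - 60) ** 2 <= 40 ** 2
        img[blob] = COLOR_EOSIN
        return img.astype(np.uint8), blob

    def test_blob_recovered_with_high_iou(self):
        img, blob = self._blob_image()
        mask = tissue_mask(img)
        iou = (mask & blob).sum() / (mask | blob).sum()
        assert iou >= 0.95

    def test_roi_intersection(self):
        img, blob = self._blob_image()
        roi = np.zeros(blob.shape, dtype=bool)
        roi[:, :60] = True
        mask = tissue_mask(img, roi=roi)
        assert not mask[:, 60:].any()

    def test_no_tissue_gives_empty_mask(self):
        img = np.full((50, 50, 3), 240, dtype=np.uint8)
        assert not tissue_mask(img).any()


class TestRigidRegister:
    def _shape_mask(self):
        mask = np.zeros((128, 128), dtype=bool)
        mask[30:90, 40:100] = True
        mask[20:30, 60:70] = True  # break rotational symmetry
        return mask

    def test_identity_for_identical_masks(self):
        m = self._shape_mask()
        tr = rigid_register(m, m)
        assert abs(tr.angle_deg) <= 0.5
        assert np.hypot(*tr.shift) <= 1.0
        assert tr.overlap > 0.99

    def test_known_rotation_and_shift_recovered(self):
        from skimage.transform import rotate

        fixed = self._shape_mask()
        moving = rotate(fixed.astype(float), -10.0, order=0) > 0.5
        moving = ndimage.shift(moving.astype(float), (-15, 10), order=0) > 0.5
        tr = rigid_register(moving, fixed)
        assert tr.angle_deg == pytest.approx(10.0, abs=1.0)
        moved = tr.apply(moving)
        dice = 2 * (moved & fixed).sum() / (moved.sum() + fixed.sum())
        assert dice > 0.95

    def test_disjoint_masks_flagged(self):
        a = np.zeros((64, 64), dtype=bool)
        b = np.zeros((64, 64), dtype=bool)
        a[2:6, 2:6] = True
        b[50:60, 50:60] = True
        tr = rigid_register(a, b)
        assert tr.warning


class TestDensityMap:
    def brute_force_count(self, mask, r, c, half):
        lab, _ = ndimage.label(mask, structure=np.ones((3, 3), int))
        win = lab[max(r - half, 0): r + half + 1, max(c - half, 0): c + half + 1]
        vals = set(np.unique(win)) - {0}
        return len(vals)

    def test_single_central_object(self):
        mask = np.zeros((201, 201), dtype=bool)
        mask[99:102, 99:102] = True
        dm = density_map(mask, "count", window_um=150.0, pixel_size_um=1.0)
        assert dm[100, 100] == 1
        assert dm[100, 100 + 75 + 1] == 1  # window edge touches the object
        assert dm[100, 100 + 75 + 3] == 0  # beyond half-window + object radius

    def test_empty_mask_all_zero(self):
        assert not density_map(np.zeros((50, 50), bool), "count",
                               pixel_size_um=4.0).any()

    def test_matches_brute_force_on_random_mask(self, rng):
        mask = rng.random((200, 200)) < 0.02
        dm = density_map(mask, "count", window_um=30.0, pixel_size_um=1.0)
        half = 15  # int(30/1)//2
        for r, c in rng.integers(0, 200, size=(200, 2)):
            assert dm[r, c] == self.brute_force_count(mask, r, c, half)

    def test_percent_area_uniform_interior(self):
        mask = np.ones((100, 100), dtype=bool)
        dm = density_map(mask, "percent_area", window_um=30.0, pixel_size_um=1.0)
        np.testing.assert_allclose(dm, 100.0)

    def test_translation_equivariance_interior(self, rng):
        mask = rng.random((120, 120)) < 0.03
        dm = density_map(mask, "count", window_um=20.0, pixel_size_um=1.0)
        shifted = np.roll(mask, (7, -5), axis=(0, 1))
        dm2 = density_map(shifted, "count", window_um=20.0, pixel_size_um=1.0)
        np.testing.assert_allclose(dm2[30:-30, 30:-30],
                                   np.roll(dm, (7, -5), axis=(0, 1))[30:-30, 30:-30])

    def test_sparse_evaluation_equals_dense_map(self, rng):
        mask = rng.random((150, 150)) < 0.02
        dm = density_map(mask, "count", window_um=40.0, pixel_size_um=1.0)
        centers = rng.integers(0, 150, size=(100, 2))
        sparse = density_at(mask, centers, "count", window_um=40.0,
                            pixel_size_um=1.0)
        np.testing.assert_allclose(sparse, dm[tuple(centers.T)])

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            density_map(np.zeros((10, 10), bool), "count", window_um=2.0,
                        pixel_size_um=1.0)


class TestDownsample:
    def test_constant_map_stays_constant(self):
        out = downsample_density(np.full((500, 500), 3.0), 0.01)
        assert np.all(out == 3.0)

    def test_output_shape_arithmetic(self):
        out = downsample_density(np.zeros((1000, 1000)), 0.01)
        assert out.shape == (10, 10)

    def test_values_subset_of_original(self, rng):
        arr = rng.random((300, 300))
        out = downsample_density(arr, 0.05)
        assert np.isin(out, arr).all()

    def test_too_small_output_rejected(self):
        with pytest.raises(ValueError):
            downsample_density(np.zeros((100, 100)), 0.01)

    @pytest.mark.parametrize("factor", [0.0, 1.0, 1.5])
    def test_invalid_factor_rejected(self, factor):
        with pytest.raises(ValueError):
            downsample_density(np.zeros((100, 100)), factor)


class TestHistologyLabels:
    @pytest.mark.parametrize("vessels,nuclei,expected", [
        (5.5, 142.3, "HV-HC"),
        (0.7, 17.8, "LV-LC"),
        (2.2, 109.5, "LV-HC"),
        (3.0, 100.0, "LV-LC"),  # boundary equality -> low side
    ])
    def test_threshold_rules(self, vessels, nuclei, expected):
        assert label_habitats_histology({"vessels": vessels,
                                         "nuclei": nuclei}) == expected


class TestStackFromMasks:
    def test_matches_dense_downsample_route(self, rng):
        masks = {s: rng.random((160, 160)) < p
                 for s, p in (("nuclei", 0.02), ("necrosis", 0.2),
                              ("ki67", 0.01), ("vessels", 0.005))}
        tissue = np.ones((160, 160), dtype=bool)
        stack = stack_from_masks(masks, tissue, pixel_size_um=4.0,
                                 downsample_factor=0.05)
        dense = density_map(masks["nuclei"], "count", pixel_size_um=4.0)
        down = downsample_density(dense, 0.05)
        np.testing.assert_allclose(stack.maps["nuclei"], down)
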