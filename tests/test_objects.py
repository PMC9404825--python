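import numpy as np
import pytest

from fibroquant.objects import (
    LabelMap,
    ObjectFilter,
    ThresholdSpec,
    apply_threshold,
    compute_threshold,
    identify_primary_objects,
    label_components,
    measure_objects,
    objects_to_mask,
    smooth_gaussian,
)
from fibroquant.raster_core import BinaryMask, GrayImage, ValidityMask
from oracles import exhaustive_otsu, flood_fill_label


def disk_image(shape, centers, radius, value=0.9):
    px = np.zeros(shape)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        px[(rows - cy) ** 2 + (cols - cx) ** 2 <= radius**2] = value
    return GrayImage(px)


class TestSmoothing:
    def test_constant_preserved(self):
        img = GrayImage(np.full((9, 9), 0.4))
        out = smooth_gaussian(img, sigma=2.0)
        np.testing.assert_allclose(out.pixels, 0.4, atol=1e-12)

    def test_mass_preserved_for_central_impulse(self):
        px = np.zeros((9, 9))
        px[4, 4] = 1.0
        out = smooth_gaussian(GrayImage(px), sigma=1.0)
        assert abs(out.pixels.sum() - 1.0) < 1e-6
        assert out.pixels[4, 4] < 1.0

    def test_tiny_sigma_is_identity(self, rng):
        img = GrayImage(rng.random((8, 8)))
        out = smooth_gaussian(img, sigma=1e-3)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-6)

    def test_invalid_pixels_do_not_leak(self):
        """A huge masked-out value must not bleed into valid neighbors."""
        px = np.full((9, 9), 0.2)
        px[4, 4] = 1.0
        v = np.ones((9, 9), bool)
        v[4, 4] = False
        out = smooth_gaussian(GrayImage(px), sigma=1.5, validity=ValidityMask(v))
        np.testing.assert_allclose(out.pixels[v], 0.2, atol=1e-9)
        assert out.pixels[4, 4] == 0.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(GrayImage(np.zeros((3, 3))), sigma=0.0)


class TestThresholdSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec(method="magic")
        with pytest.raises(ValueError):
            ThresholdSpec(correction_factor=0.0)
        with pytest.raises(ValueError):
            ThresholdSpec(lower_bound=0.8, upper_bound=0.2)


class TestComputeThreshold:
    def test_otsu_matches_exhaustive_oracle(self, rng):
        spec = ThresholdSpec(method="otsu")
        for _ in range(50):
            img = GrayImage(rng.random((12, 12)))
            t = compute_threshold(img, spec)
            assert t == exhaustive_otsu(img.pixels.ravel())

    def test_otsu_bimodal_lies_between_modes(self, rng):
        values = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)])
        img = GrayImage(rng.permutation(values).reshape(10, 10))
        t = compute_threshold(img, ThresholdSpec(method="otsu"))
        assert 0.1 < t < 0.9

    def test_fixed_passthrough(self, rng):
        img = GrayImage(rng.random((4, 4)))
        spec = ThresholdSpec(method="fixed", fixed_value=0.4)
        assert compute_threshold(img, spec) == 0.4

    def test_correction_then_clamp(self):
        img = GrayImage(np.full((4, 4), 0.30))
        spec = ThresholdSpec(method="otsu", correction_factor=2.0, upper_bound=0.5)
        # constant image -> otsu returns the constant, then 0.30*2 clamps at 0.5
        assert compute_threshold(img, spec) == 0.5

    def test_invalid_pixels_never_influence_threshold(self, rng):
        """Duplicating the image and changing only invalid pixels leaves the
        threshold unchanged."""
        px = rng.random((10, 10))
        v = ValidityMask(rng.random((10, 10)) > 0.4)
        altered = px.copy()
        altered[~v.pixels] = rng.random((~v.pixels).sum())
        spec = ThresholdSpec(method="otsu")
        assert compute_threshold(GrayImage(px), spec, v) == compute_threshold(
            GrayImage(altered), spec, v
        )

    def test_zero_valid_pixels_rejected(self):
        v = ValidityMask(np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            compute_threshold(GrayImage(np.zeros((3, 3))), ThresholdSpec(), v)

    def test_constant_image_returns_constant(self):
        img = GrayImage(np.full((5, 5), 0.37))
        assert compute_threshold(img, ThresholdSpec(method="otsu")) == 0.37


class TestApplyThreshold:
    def test_extremes(self, rng):
        img = GrayImage(rng.uniform(0.1, 0.9, (5, 5)))
        assert not apply_threshold(img, 1.0).pixels.any()
        assert apply_threshold(img, 0.0).pixels.all()

    def test_matches_pixelwise_comparison(self, rng):
        img = GrayImage(rng.random((7, 7)))
        v = ValidityMask(rng.random((7, 7)) > 0.3)
        mask = apply_threshold(img, 0.5, v)
        np.testing.assert_array_equal(mask.pixels, (img.pixels > 0.5) & v.pixels)


class TestLabeling:
    def test_empty_mask(self):
        labels = label_components(BinaryMask(np.zeros((4, 4), bool)))
        assert labels.n_objects == 0

    def test_diagonal_connectivity(self):
        m = np.zeros((3, 3), bool)
        m[0, 0] = m[1, 1] = True
        assert label_components(BinaryMask(m), connectivity=4).n_objects == 2
        assert label_components(BinaryMask(m), connectivity=8).n_objects == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(20):
            m = rng.random((16, 16)) < 0.45
            got = label_components(BinaryMask(m), connectivity)
            expected = flood_fill_label(m, connectivity)
            np.testing.assert_array_equal(got.pixels, expected)

    def test_labels_follow_raster_order(self):
        m = np.zeros((5, 5), bool)
        m[4, 0] = True  # later in raster order
        m[0, 4] = True  # earlier
        labels = label_components(BinaryMask(m))
        assert labels.pixels[0, 4] == 1
        assert labels.pixels[4, 0] == 2


class TestIdentifyPrimaryObjects:
    SPEC = ThresholdSpec(method="fixed", fixed_value=0.5)

    def test_blank_image_has_no_objects(self):
        img = GrayImage(np.zeros((16, 16)))
        out = identify_primary_objects(img, ObjectFilter(), ThresholdSpec(method="otsu"))
        assert out.n_objects == 0

    def test_three_disks_within_filter(self):
        img = disk_image((48, 48), [(10, 10), (10, 36), (36, 24)], radius=6)
        flt = ObjectFilter(min_diameter=8, max_diameter=20)
        out = identify_primary_objects(img, flt, self.SPEC)
        assert out.n_objects == 3

    def test_small_disk_filtered_by_equivalent_diameter(self):
        img = disk_image((16, 16), [(8, 8)], radius=2)
        flt = ObjectFilter(min_diameter=8, max_diameter=100)
        out = identify_primary_objects(img, flt, self.SPEC)
        assert out.n_objects == 0

    def test_border_object_kept_by_default_dropped_on_request(self):
        img = disk_image((20, 20), [(0, 10)], radius=5)
        flt_keep = ObjectFilter(min_diameter=2, max_diameter=50, keep_border=True)
        flt_drop = ObjectFilter(min_diameter=2, max_diameter=50, keep_border=False)
        assert identify_primary_objects(img, flt_keep, self.SPEC).n_objects == 1
        assert identify_primary_objects(img, flt_drop, self.SPEC).n_objects == 0

    def test_fill_holes_absorbs_lumen(self):
        px = np.zeros((20, 20))
        rows, cols = np.mgrid[0:20, 0:20]
        r2 = (rows - 10) ** 2 + (cols - 10) ** 2
        px[(r2 <= 64) & (r2 > 25)] = 0.9  # annulus only
        flt = ObjectFilter(min_diameter=2, max_diameter=50, fill_holes=True)
        out = identify_primary_objects(GrayImage(px), flt, self.SPEC)
        assert out.n_objects == 1
        assert out.pixels[10, 10] > 0  # lumen joined to its rim

    def test_diameter_filter_monotone(self, rng):
        img = GrayImage((rng.random((32, 32)) > 0.6).astype(float))
        tight = ObjectFilter(min_diameter=3, max_diameter=6, fill_holes=False)
        loose = ObjectFilter(min_diameter=1, max_diameter=100, fill_holes=False)
        n_tight = identify_primary_objects(img, tight, self.SPEC).n_objects
        n_loose = identify_primary_objects(img, loose, self.SPEC).n_objects
        assert n_loose >= n_tight

    def test_idempotent_on_own_rendering(self):
        img = disk_image((48, 48), [(12, 12), (30, 30)], radius=5)
        flt = ObjectFilter(min_diameter=2, max_diameter=50)
        first = identify_primary_objects(img, flt, self.SPEC)
        rendering = GrayImage(objects_to_mask(first).pixels.astype(float))
        second = identify_primary_objects(rendering, flt, self.SPEC)
        assert second.n_objects == first.n_objects


class TestMeasureObjects:
    def test_square_object(self):
        px = np.zeros((5, 5), dtype=np.int32)
        px[1:4, 1:4] = 1
        df = measure_objects(LabelMap(px, 1))
        assert df.loc[0, "area"] == 9
        assert df.loc[0, "centroid_row"] == 2.0
        np.testing.assert_allclose(df.loc[0, "equivalent_diameter"], 2 * np.sqrt(9 / np.pi))

    def test_empty_map(self):
        df = measure_objects(LabelMap(np.zeros((3, 3), dtype=np.int32), 0))
        assert len(df) == 0

    def test_areas_match_brute_force_tally(self, rng):
        m = rng.random((20, 20)) < 0.4
        labels = label_components(BinaryMask(m))
        df = measure_objects(labels)
        assert df["area"].sum() == m.sum()
        for _, row in df.iterrows():
            assert row["area"] == int((labels.pixels == row["label"]).sum())

    def test_objects_to_mask_positions(self):
        px = np.zeros((4, 4), dtype=np.int32)
        px[2, 1:4] = 1
        mask = objects_to_mask(LabelMap(px, 1))
        np.testing.assert_array_equal(mask.pixels, px > 0)
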