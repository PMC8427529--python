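import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from lamincycle.imaging_core import (
    BinaryMask,
    CellFeatures,
    EmptyMaskError,
    FlatImageError,
    MultiChannelCellImage,
    extract_features,
    features_to_frame,
    gradient_rms,
    morph_mask,
    perinuclear_mask,
    read_cell_tiff,
    read_features_csv,
    region_aspect_ratio,
    spot_count,
    threshold_mask,
    write_cell_tiff,
    write_features_csv,
)


def disk(shape, center, radius):
    rows, cols = np.indices(shape)
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


class TestThresholdMask:
    def test_sixty_percent_of_peak(self):
        mask = threshold_mask(np.array([[0.0, 10.0], [6.0, 4.0]]), 0.6)
        assert mask.grid.tolist() == [[False, True], [True, False]]

    @given(
        grid=hnp.arrays(float, (16, 16), elements=st.floats(0, 100)),
        fraction=st.floats(0.05, 0.95),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_per_pixel_oracle(self, grid, fraction):
        """Vectorized thresholding equals an exhaustive per-pixel check."""
        if grid.max() <= 0:
            return
        mask = threshold_mask(grid, fraction)
        cut = fraction * grid.max()
        for r in range(16):
            for c in range(16):
                assert mask.grid[r, c] == (grid[r, c] >= cut)

    def test_flat_image_rejected(self):
        with pytest.raises(FlatImageError):
            threshold_mask(np.zeros((4, 4)), 0.6)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2])
    def test_fraction_outside_open_interval_rejected(self, fraction):
        with pytest.raises(ValueError):
            threshold_mask(np.ones((3, 3)), fraction)


class TestMorphMask:
    def test_dilate_single_pixel_gives_disk_cross(self):
        grid = np.zeros((5, 5), dtype=bool)
        grid[2, 2] = True
        out = morph_mask(BinaryMask(grid), "dilate", 1)
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 1:4] = True
        expected[1:4, 2] = True
        assert np.array_equal(out.grid, expected)

    def test_erode_square_to_center(self):
        grid = np.zeros((9, 9), dtype=bool)
        grid[2:7, 2:7] = True
        out = morph_mask(BinaryMask(grid), "erode", 2)
        assert out.area == 1 and out.grid[4, 4]

    @given(grid=hnp.arrays(bool, (20, 20)), k=st.integers(1, 3))
    @settings(max_examples=30, deadline=None)
    def test_erosion_dilation_sandwich(self, grid, k):
        """erode(m,k) is a subset of m, which is a subset of dilate(m,k)."""
        m = BinaryMask(grid)
        eroded = morph_mask(m, "erode", k)
        dilated = morph_mask(m, "dilate", k)
        assert not (eroded.grid & ~m.grid).any()
        assert not (m.grid & ~dilated.grid).any()


class TestPerinuclearMask:
    def test_ring_around_disk(self):
        nucleus = BinaryMask(disk((40, 40), (20, 20), 10))
        ring = perinuclear_mask(nucleus)
        rows, cols = np.nonzero(ring.grid)
        radii = np.hypot(rows - 20.0, cols - 20.0)
        # Ring = dilate(1) minus erode(2): spans roughly radii 8-11.
        assert radii.min() >= 7.0 and radii.max() <= 11.5
        assert ring.area > 0

    @given(grid=hnp.arrays(bool, (24, 24)))
    @settings(max_examples=30, deadline=None)
    def test_ring_excludes_eroded_interior(self, grid):
        m = BinaryMask(grid)
        if not grid.any():
            return
        ring = perinuclear_mask(m)
        interior = morph_mask(m, "erode", 2)
        assert not (ring.grid & interior.grid).any()

    def test_tiny_nucleus_ring_equals_dilation(self):
        grid = np.zeros((11, 11), dtype=bool)
        grid[5, 5] = True  # smaller than the erosion element
        ring = perinuclear_mask(BinaryMask(grid))
        assert np.array_equal(ring.grid, morph_mask(BinaryMask(grid), "dilate", 1).grid)

    def test_empty_nucleus_rejected(self):
        with pytest.raises(EmptyMaskError):
            perinuclear_mask(BinaryMask(np.zeros((5, 5), dtype=bool)))


class TestSpotCount:
    def test_single_blob(self):
        img = np.zeros((32, 32))
        img[disk(img.shape, (16, 16), 4)] = 1.0
        assert spot_count(img) == 1

    def test_two_separated_blobs(self):
        img = np.zeros((32, 32))
        img[disk(img.shape, (8, 8), 4)] = 1.0
        img[disk(img.shape, (24, 24), 4)] = 1.0
        assert spot_count(img) == 2

    def test_range_mask_drops_small_component(self):
        img = np.zeros((32, 32))
        img[disk(img.shape, (8, 8), 4)] = 1.0
        img[24, 24] = 1.0  # single-pixel speck, below min area
        assert spot_count(img, min_component_area=10) == 1


class TestExtractFeatures:
    def _image_with_masks(self, cell_grid, nucleus_grid=None):
        shape = cell_grid.shape
        if nucleus_grid is None:
            nucleus_grid = disk(shape, (shape[0] // 2, shape[1] // 2), 5)
        lamin = np.where(nucleus_grid, 1.0, 0.1)
        channels = {
            "brightfield": np.where(cell_grid, 0.6, 0.3),
            "laminA": lamin,
            "tubulin": np.where(cell_grid, 0.5, 0.0),
            "chromatin": np.where(nucleus_grid, 0.9, 0.02),
        }
        image = MultiChannelCellImage("c1", channels)
        masks = {"cell": BinaryMask(cell_grid), "nucleus": BinaryMask(nucleus_grid)}
        return image, masks

    def test_circle_aspect_ratio_is_one(self):
        assert region_aspect_ratio(BinaryMask(disk((64, 64), (32, 32), 15))) == pytest.approx(1.0, abs=0.02)

    def test_two_to_one_ellipse_aspect_ratio(self):
        rows, cols = np.indices((64, 64))
        ellipse = ((cols - 32) / 20.0) ** 2 + ((rows - 32) / 10.0) ** 2 <= 1
        assert region_aspect_ratio(BinaryMask(ellipse)) == pytest.approx(0.5, abs=0.02)

    def test_single_pixel_region_degenerates_to_one(self):
        grid = np.zeros((5, 5), dtype=bool)
        grid[2, 2] = True
        assert region_aspect_ratio(BinaryMask(grid)) == 1.0

    def test_constant_image_has_zero_gradient_rms(self):
        mask = BinaryMask(disk((32, 32), (16, 16), 8))
        assert gradient_rms(np.full((32, 32), 3.0), mask) == 0.0

    def test_feature_values_and_determinism(self):
        cell = disk((64, 64), (32, 32), 20)
        image, masks = self._image_with_masks(cell)
        f1 = extract_features(image, masks)
        f2 = extract_features(image, masks)
        assert f1 == f2  # bit-identical on identical inputs
        assert f1.area == int(cell.sum())
        assert f1.centroid_x == pytest.approx(32.0, abs=0.5)
        assert f1.nuclear_spot_count == 1

    def test_empty_mask_rejected(self):
        image, masks = self._image_with_masks(disk((64, 64), (32, 32), 20))
        masks["cell"] = BinaryMask(np.zeros((64, 64), dtype=bool))
        with pytest.raises(EmptyMaskError):
            extract_features(image, masks)


class TestDomainTypes:
    def test_mismatched_channel_shapes_rejected(self):
        with pytest.raises(ValueError):
            MultiChannelCellImage("c", {"laminA": np.ones((4, 4)), "chromatin": np.ones((5, 5))})

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            MultiChannelCellImage("c", {"laminA": -np.ones((4, 4))})

    def test_aspect_ratio_bounds_enforced(self):
        with pytest.raises(ValueError):
            CellFeatures("c", 1, 1.5, 0, 0, {}, {}, 0)


class TestIO:
    def test_tiff_roundtrip(self, tmp_path, interphase_cell):
        path = tmp_path / "cell.tif"
        write_cell_tiff(interphase_cell.image, path)
        back = read_cell_tiff(path)
        for name, grid in interphase_cell.image.channels.items():
            np.testing.assert_allclose(back.channel(name), grid, rtol=1e-6)

    def test_features_csv_roundtrip(self, tmp_path, gallery):
        features = [entry["features"] for entry in gallery[:5]]
        path = tmp_path / "features.csv"
        write_features_csv(features, path)
        back = read_features_csv(path)
        assert len(back) == len(features)
        for orig, rt in zip(features, back):
            assert rt.cell_id == orig.cell_id
            assert rt.area == orig.area
            assert rt.nuclear_spot_count == orig.nuclear_spot_count
            assert rt.max_pixel["perinuclear"] == pytest.approx(orig.max_pixel["perinuclear"])
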