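import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from spatialplex.errors import ConfigError, DataError
from spatialplex.segment import (
    ImageGrid,
    LabelMask,
    SegmentationParams,
    compensate_spillover,
    detect_maxima,
    grow_regions,
    quantify_cells,
)


def gaussian_blob(shape, center, sigma, amp=100.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return amp * np.exp(-(((xx - center[1]) ** 2 + (yy - center[0]) ** 2) / (2 * sigma**2)))


PARAMS = SegmentationParams(smoothing_sigma=1.0, maxima_min_distance=3, maxima_min_intensity=0.1)


class TestDetectMaxima:
    def test_single_blob_single_seed(self):
        img = gaussian_blob((40, 40), (17, 23), sigma=3)
        seeds = detect_maxima(img, PARAMS)
        assert len(seeds) == 1
        assert abs(seeds[0][0] - 17) <= 1 and abs(seeds[0][1] - 23) <= 1

    def test_two_blobs_exhaustive_scan_oracle(self):
        img = gaussian_blob((60, 60), (15, 15), 3) + gaussian_blob((60, 60), (45, 45), 3)
        seeds = detect_maxima(img, PARAMS)
        assert len(seeds) == 2
        # oracle: exhaustive strict-maxima scan of the smoothed raster
        smoothed = ndimage.gaussian_filter(img, PARAMS.smoothing_sigma)
        d = PARAMS.maxima_min_distance
        oracle = []
        for r in range(smoothed.shape[0]):
            for c in range(smoothed.shape[1]):
                v = smoothed[r, c]
                if v <= PARAMS.maxima_min_intensity * smoothed.max():
                    continue
                strict = True
                for dr in range(-d, d + 1):
                    for dc in range(-d, d + 1):
                        if dr == 0 and dc == 0 or dr * dr + dc * dc > d * d:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < smoothed.shape[0] and 0 <= cc < smoothed.shape[1]:
                            if smoothed[rr, cc] >= v:
                                strict = False
                if strict:
                    oracle.append((r, c))
        assert sorted(seeds) == sorted(oracle)

    def test_constant_raster_no_seeds(self):
        assert detect_maxima(np.full((20, 20), 5.0), PARAMS) == []

    def test_all_zero_raster_empty(self):
        assert detect_maxima(np.zeros((10, 10)), PARAMS) == []

    def test_sorted_by_descending_intensity(self):
        img = gaussian_blob((60, 60), (15, 15), 3, amp=50) + gaussian_blob(
            (60, 60), (45, 45), 3, amp=100
        )
        seeds = detect_maxima(img, PARAMS)
        assert seeds[0] == (45, 45) or abs(seeds[0][0] - 45) <= 1

    def test_monotone_in_min_intensity(self):
        rng = np.random.default_rng(0)
        img = ndimage.gaussian_filter(rng.uniform(0, 1, (50, 50)), 1.5)
        counts = []
        for thr in (0.0, 0.3, 0.6, 0.9):
            p = SegmentationParams(
                smoothing_sigma=0.5, maxima_min_distance=2, maxima_min_intensity=thr
            )
            counts.append(len(detect_maxima(img, p)))
        assert counts == sorted(counts, reverse=True)


class TestGrowRegions:
    def test_disc_area_lattice_point_oracle(self):
        # oracle: enumerate lattice points within Euclidean radius 5
        r = 5
        oracle_area = sum(
            1
            for dx in range(-r, r + 1)
            for dy in range(-r, r + 1)
            if dx * dx + dy * dy <= r * r
        )
        img = np.ones((30, 30)) * 100.0
        mask = grow_regions(img, [(15, 15)], PARAMS)
        assert (mask.labels == 1).sum() == oracle_area

    def test_two_distant_seeds_disjoint(self):
        img = np.ones((40, 40)) * 100.0
        mask = grow_regions(img, [(10, 10), (10, 20)], PARAMS)
        a = mask.labels == 1
        b = mask.labels == 2
        assert a.sum() > 0 and b.sum() > 0 and not (a & b).any()

    def test_empty_seed_list(self):
        mask = grow_regions(np.ones((10, 10)), [], PARAMS)
        assert mask.labels.max() == 0

    def test_regions_within_growth_radius_of_seed(self):
        img = gaussian_blob((50, 50), (20, 20), 4) + gaussian_blob((50, 50), (35, 35), 4)
        seeds = detect_maxima(img, PARAMS)
        mask = grow_regions(img, seeds, PARAMS)
        for label, (sr, sc) in mask.seeds.items():
            rows, cols = np.nonzero(mask.labels == label)
            d = np.sqrt((rows - sr) ** 2 + (cols - sc) ** 2)
            assert d.max() <= PARAMS.growth_radius + 1e-9

    def test_size_cutoff_drops_small_regions(self):
        img = np.zeros((60, 60))
        img += gaussian_blob((60, 60), (20, 20), 4, amp=100)
        img += gaussian_blob((60, 60), (40, 40), 0.8, amp=100)  # tiny peak
        params = SegmentationParams(
            smoothing_sigma=1.0, maxima_min_distance=3, maxima_min_intensity=0.05,
            size_cutoff_factor=0.0, intensity_floor_frac=0.3,
        )
        n_all = grow_regions(img, detect_maxima(img, params), params).n_regions
        params_cut = SegmentationParams(
            smoothing_sigma=1.0, maxima_min_distance=3, maxima_min_intensity=0.05,
            size_cutoff_factor=0.9, intensity_floor_frac=0.3,
        )
        n_cut = grow_regions(img, detect_maxima(img, params_cut), params_cut).n_regions
        assert n_all == 2 and n_cut == 1

    def test_labels_contiguous_and_4_connected(self):
        img = gaussian_blob((50, 50), (15, 15), 4) + gaussian_blob((50, 50), (35, 35), 4)
        mask = grow_regions(img, detect_maxima(img, PARAMS), PARAMS)
        labels = np.unique(mask.labels)
        assert list(labels) == list(range(mask.n_regions + 1))
        four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for label in range(1, mask.n_regions + 1):
            assert ndimage.label(mask.labels == label, structure=four)[1] == 1


class TestQuantifyCells:
    def _mask_and_image(self):
        img = np.ones((30, 30)) * 100.0
        mask = grow_regions(img, [(15, 15)], PARAMS)
        grid = ImageGrid(
            channels={"DNA": img, "CD3": np.full((30, 30), 7.0)}, pixel_size=0.5
        )
        return mask, grid

    def test_constant_channel_mean(self):
        mask, grid = self._mask_and_image()
        cells = quantify_cells(mask, grid)
        assert len(cells) == 1
        assert cells["CD3"].iloc[0] == pytest.approx(7.0)

    def test_centroid_of_symmetric_disc(self):
        mask, grid = self._mask_and_image()
        cells = quantify_cells(mask, grid)
        assert cells["x_um"].iloc[0] == pytest.approx((15 + 0.5) * 0.5, abs=0.25)
        assert cells["y_um"].iloc[0] == pytest.approx((15 + 0.5) * 0.5, abs=0.25)

    def test_area_units(self):
        mask, grid = self._mask_and_image()
        cells = quantify_cells(mask, grid)
        n_px = (mask.labels == 1).sum()
        assert cells["area_um2"].iloc[0] == pytest.approx(n_px * 0.5**2)

    def test_shape_mismatch_rejected(self):
        mask, _ = self._mask_and_image()
        grid = ImageGrid(channels={"CD3": np.zeros((10, 10))}, pixel_size=1.0)
        with pytest.raises(DataError, match="shape"):
            quantify_cells(mask, grid)


class TestSpillover:
    def _two_adjacent_cells(self):
        labels = np.zeros((4, 8), dtype=np.int32)
        labels[:, 1:4] = 1
        labels[:, 4:7] = 2
        mask = LabelMask(labels=labels, seeds={1: (1, 2), 2: (1, 5)})
        cells = pd.DataFrame({"cell_id": [1, 2], "CD3": [10.0, 2.0]})
        return cells, mask

    def test_hand_computed_correction(self):
        cells, mask = self._two_adjacent_cells()
        out = compensate_spillover(cells, mask, alpha=0.5, markers=["CD3"])
        assert out["CD3"].tolist() == [9.0, 0.0]  # 10-0.5*2; max(0, 2-0.5*10)

    def test_alpha_zero_identity(self):
        cells, mask = self._two_adjacent_cells()
        out = compensate_spillover(cells, mask, alpha=0.0, markers=["CD3"])
        pd.testing.assert_frame_equal(out, cells)

    def test_isolated_cell_unchanged(self):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[1:3, 1:3] = 1
        cells = pd.DataFrame({"cell_id": [1], "CD3": [10.0]})
        out = compensate_spillover(cells, LabelMask(labels=labels), alpha=0.9, markers=["CD3"])
        assert out["CD3"].iloc[0] == 10.0

    def test_never_negative(self, rng):
        labels = np.arange(1, 26, dtype=np.int32).reshape(5, 5)
        cells = pd.DataFrame(
            {"cell_id": np.arange(1, 26), "CD3": rng.uniform(0, 100, 25)}
        )
        out = compensate_spillover(cells, LabelMask(labels=labels), alpha=1.0, markers=["CD3"])
        assert (out["CD3"] >= 0).all()

    def test_bad_alpha_rejected(self):
        cells, mask = self._two_adjacent_cells()
        with pytest.raises(ConfigError):
            compensate_spillover(cells, mask, alpha=1.5)


def test_recovery_on_planted_nuclei():
    from spatialplex.simulate import TissueConfig, render_image, simulate_tissue

    config = TissueConfig(
        architecture="diffuse", roi_size_um=(120.0, 120.0), n_cells=50,
        composition={"Helper T": 1.0}, min_spacing_um=9.0, seed=5,
    )
    cells, truth = simulate_tissue(config)
    img = render_image(cells, truth, pixel_size=1.0, roi_size_um=(120.0, 120.0), noise_sd=0.5)
    params = SegmentationParams(
        smoothing_sigma=1.0, maxima_min_distance=3, maxima_min_intensity=0.05
    )
    seeds = detect_maxima(img.channels["DNA"], params)
    mask = grow_regions(img.channels["DNA"], seeds, params)
    assert abs(mask.n_regions - 50) / 50 <= 0.05
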