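"""Image quantification: illumination correction, denoising, phase
segmentation, intensity measurement, and marker-to-cell linkage."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import osmoshock as osk
from osmoshock.segmentation import SegmentationConfig, objects_to_frame

PIXEL_SIZE = 0.16  # um/px


@pytest.fixture(scope="module")
def flat_fixture(default_config):
    """10-cell field, flat illumination, no noise: area_cv=0 so each
    cell's rendered total fluorescence is alpha_true * N_c exactly."""
    table = osk.generate_cells(
        default_config.replace(n_cells=10, area_cv=0.0, density_noise_cv=0.0)
    )
    phase, fluor, mask = osk.generate_image_pair(
        table, field_shape=(512, 512), seed=21, pixel_size_um=PIXEL_SIZE,
        background=300.0,
    )
    return table, phase, fluor, mask


@pytest.fixture(scope="module")
def gradient_fixture(default_config):
    """Same field under a 2x left-to-right illumination gradient."""
    table = osk.generate_cells(
        default_config.replace(n_cells=10, area_cv=0.0, density_noise_cv=0.0)
    )
    phase, fluor, mask = osk.generate_image_pair(
        table, field_shape=(512, 512), illumination_gradient=2.0, seed=21,
        pixel_size_um=PIXEL_SIZE, background=300.0,
    )
    return table, phase, fluor, mask


class TestCorrectIllumination:
    def test_flat_image_unchanged(self):
        img = np.full((64, 64), 7.0)
        np.testing.assert_allclose(osk.correct_illumination(img), img, rtol=1e-9)

    def test_negative_pixels_rejected(self):
        img = np.full((8, 8), 1.0)
        img[0, 0] = -1
        with pytest.raises(ValueError):
            osk.correct_illumination(img)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            osk.correct_illumination(np.zeros((8, 8)))

    def test_global_mean_preserved(self, gradient_fixture):
        _, _, fluor, _ = gradient_fixture
        corrected = osk.correct_illumination(fluor + 1.0)
        assert corrected.mean() == pytest.approx((fluor + 1.0).mean(), rel=1e-9)

    def test_gradient_removed_with_flat_field(self, gradient_fixture, flat_fixture):
        # dividing by the recorded illumination profile restores the flat
        # field's per-cell means to within 2%
        table, _, grad_fluor, mask = gradient_fixture
        _, _, flat_fluor, _ = flat_fixture
        ncols = grad_fluor.shape[1]
        profile = np.tile(np.linspace(1.0, 2.0, ncols), (grad_fluor.shape[0], 1))
        profile /= profile.mean()
        corrected = osk.correct_illumination(grad_fluor, flat_field=profile)
        ratios = np.array([
            corrected[mask == label].mean() / flat_fluor[mask == label].mean()
            for label in range(1, int(mask.max()) + 1)
        ])
        np.testing.assert_allclose(ratios, ratios.mean(), rtol=0.02)

    def test_self_estimate_reduces_gradient_bias(self, gradient_fixture, flat_fixture):
        table, _, grad_fluor, mask = gradient_fixture
        _, _, flat_fluor, _ = flat_fixture
        corrected = osk.correct_illumination(grad_fluor)
        err_raw, err_corr = [], []
        for label in range(1, int(mask.max()) + 1):
            truth = flat_fluor[mask == label].mean()
            err_raw.append(abs(grad_fluor[mask == label].mean() / truth - 1))
            err_corr.append(abs(corrected[mask == label].mean() / truth - 1))
        assert np.median(err_corr) < np.median(err_raw)


class TestDenoise:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 5.0)
        np.testing.assert_allclose(osk.denoise(img), img)

    def test_mean_preserved_under_symmetric_noise(self, flat_fixture):
        _, _, fluor, _ = flat_fixture
        noisy = fluor + 1000.0 + np.random.default_rng(0).normal(0, 10, fluor.shape)
        out = osk.denoise(noisy)
        assert out.mean() == pytest.approx(noisy.mean(), rel=1e-3)

    def test_empty_image_passthrough(self):
        out = osk.denoise(np.zeros((0, 0)))
        assert out.size == 0

    def test_salt_and_pepper_error_reduced(self, flat_fixture):
        _, _, fluor, mask = flat_fixture
        rng = np.random.default_rng(1)
        corrupted = fluor.copy()
        hits = rng.random(fluor.shape) < 0.02
        corrupted[hits] = fluor.max() * 2
        cleaned = osk.denoise(corrupted)
        err_bad, err_clean = [], []
        for label in range(1, int(mask.max()) + 1):
            truth = fluor[mask == label].mean()
            err_bad.append(abs(corrupted[mask == label].mean() - truth))
            err_clean.append(abs(cleaned[mask == label].mean() - truth))
        assert np.mean(err_clean) < np.mean(err_bad)


class TestSegmentPhase:
    def test_blank_field_empty_mask(self):
        mask = osk.segment_phase(np.full((64, 64), 0.8), PIXEL_SIZE)
        assert mask.max() == 0

    def test_recovers_ten_cells_with_good_overlap(self, flat_fixture):
        _, phase, _, truth_mask = flat_fixture
        mask = osk.segment_phase(phase, PIXEL_SIZE)
        assert mask.max() == 10
        for label in range(1, 11):
            truth = truth_mask == label
            overlap = [
                (mask == m).sum() and ((mask == m) & truth).sum()
                / ((mask == m) | truth).sum()
                for m in np.unique(mask[truth]) if m > 0
            ]
            assert max(overlap) >= 0.6

    def test_giant_region_filtered_by_area_window(self):
        phase = np.full((128, 128), 0.8)
        phase[8:120, 8:120] = 0.2  # one region far above max_area_um2
        mask = osk.segment_phase(phase, PIXEL_SIZE)
        assert mask.max() == 0

    def test_invalid_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            osk.segment_phase(np.zeros((8, 8)), 0.0)


class TestMeasureCells:
    def test_uniform_cell_background_subtraction(self):
        # 100-px cell of intensity 10 over background 2 -> mean 8
        img = np.full((40, 40), 2.0)
        mask = np.zeros((40, 40), dtype=int)
        mask[10:20, 10:20] = 1
        img[10:20, 10:20] = 10.0
        (obj,) = osk.measure_cells(mask, img, pixel_size_um=1.0)
        assert obj.mean_intensity == pytest.approx(8.0)
        assert obj.total_intensity == pytest.approx(800.0)
        assert obj.area_um2 == pytest.approx(100.0)

    def test_empty_mask_empty_list(self):
        assert osk.measure_cells(np.zeros((8, 8), int), np.ones((8, 8)), 1.0) == []

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            osk.measure_cells(np.zeros((8, 8), int), np.ones((4, 4)), 1.0)

    def test_recovers_channel_counts_within_five_percent(
        self, flat_fixture, default_config
    ):
        # full chain on the noiseless flat-field fixture
        table, phase, fluor, _ = flat_fixture
        mask = osk.segment_phase(phase, PIXEL_SIZE)
        objects = osk.measure_cells(mask, fluor, PIXEL_SIZE)
        assert len(objects) == len(table)
        est = np.sort([
            o.total_intensity / default_config.alpha_true for o in objects
        ])
        truth = np.sort(table["truth__n_channels"].to_numpy())
        rel = np.abs(est - truth) / truth
        assert np.median(rel) < 0.05


class TestLinkMarkers:
    def test_single_pair(self):
        markers = [osk.Marker((5.0, 5.0), 1.0)]
        objects = [osk.SegmentedObject(1, (6.0, 6.0), 1.0, 1.0, 1.0)]
        pairs, unmatched = osk.link_markers(markers, objects)
        assert pairs == [(0, 1, pytest.approx(np.sqrt(2)), False)]
        assert unmatched == []

    def test_markers_at_centroids_all_correct(self, flat_fixture):
        _, phase, fluor, _ = flat_fixture
        mask = osk.segment_phase(phase, PIXEL_SIZE)
        objects = osk.measure_cells(mask, fluor, PIXEL_SIZE)
        markers = [osk.Marker(o.centroid, 1.0) for o in objects]
        pairs, unmatched = osk.link_markers(markers, objects)
        assert unmatched == []
        for i, label, dist, flagged in pairs:
            assert label == objects[i].label
            assert dist < 1e-9 and not flagged

    def test_greedy_matches_optimal_assignment(self):
        # brute-force oracle: minimum-total-distance assignment on small
        # well-separated instances
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = int(rng.integers(2, 9))
            centroids = rng.uniform(0, 500, (k, 2))
            jitter = rng.uniform(-3, 3, (k, 2))
            objects = [
                osk.SegmentedObject(j + 1, tuple(centroids[j]), 1.0, 1.0, 1.0)
                for j in range(k)
            ]
            order = rng.permutation(k)
            markers = [
                osk.Marker(tuple(centroids[j] + jitter[j]), 1.0) for j in order
            ]
            pairs, _ = osk.link_markers(markers, objects)
            dist = np.array([
                [np.hypot(*(np.array(m.position) - np.array(o.centroid)))
                 for o in objects] for m in markers
            ])
            rows, cols = linear_sum_assignment(dist)
            oracle = {(int(r), objects[c].label) for r, c in zip(rows, cols)}
            assert {(i, label) for i, label, _, _ in pairs} == oracle

    def test_equidistant_tie_deterministic_and_flagged(self):
        objects = [osk.SegmentedObject(1, (0.0, 0.0), 1.0, 1.0, 1.0)]
        markers = [osk.Marker((0.0, 3.0), 1.0), osk.Marker((3.0, 0.0), 0.0)]
        pairs, unmatched = osk.link_markers(markers, objects)
        assert len(pairs) == 1
        assert pairs[0][0] == 0  # lower marker index wins the tie
        assert pairs[0][3]  # ambiguous pairing is flagged
        assert unmatched == [1]

    def test_excess_markers_unmatched(self):
        objects = [osk.SegmentedObject(1, (0.0, 0.0), 1.0, 1.0, 1.0)]
        markers = [osk.Marker((0.0, float(i)), 1.0) for i in range(4)]
        pairs, unmatched = osk.link_markers(markers, objects)
        assert len(pairs) == 1 and len(unmatched) == 3

    def test_distant_pair_flagged_for_review(self):
        objects = [osk.SegmentedObject(1, (0.0, 0.0), 1.0, 1.0, 1.0)]
        markers = [osk.Marker((0.0, 100.0), 1.0)]
        pairs, _ = osk.link_markers(markers, objects)
        assert pairs[0][3]

    def test_invalid_marker_value_rejected(self):
        with pytest.raises(ValueError):
            osk.Marker((0.0, 0.0), 0.5)


def test_objects_frame_schema():
    objects = [osk.SegmentedObject(1, (2.0, 3.0), 4.0, 5.0, 20.0)]
    frame = objects_to_frame(objects)
    assert list(frame.columns) == [
        "label", "centroid_row", "centroid_col", "area_um2",
        "mean_intensity", "total_intensity",
    ]
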