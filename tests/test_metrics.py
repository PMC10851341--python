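"""Tests for ROIs, contrast, LOC, gCNR, classification and summaries."""

import dataclasses

import numpy as np
import pytest

from slscbf.beamform import BeamformedImage
from slscbf.metrics import (
    ConfusionCounts,
    EllipseROI,
    classify_mass,
    confusion_from_labels,
    contrast,
    contrast_difference,
    gcnr,
    harmonic_ratio_map,
    lag_one_coherence_map,
    mean_loc,
    roi_mask,
    select_bin_count,
    sensitivity_specificity,
    validate_roi_pair,
)
from slscbf.rf_data import AcquisitionGeometry, ChannelDataFrame

from .conftest import make_toy_frame

GEOM = AcquisitionGeometry(n_receive_elements=4, n_scan_lines=64)
SHAPE = (200, 64)  # ~3.85 mm deep x 6.3 mm wide at the default mapping


def image_from(values, mode="SLSC", band="fundamental", state="linear", geometry=GEOM):
    return BeamformedImage(np.asarray(values, float), mode, band, state, geometry)


def two_level_image(mass_value, tissue_value, mass_roi, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    values = np.full(SHAPE, float(tissue_value)) + noise * rng.standard_normal(SHAPE)
    mask = roi_mask(mass_roi, GEOM, SHAPE)
    values[mask] = mass_value + noise * rng.standard_normal(mask.sum())
    return image_from(values)


MASS = EllipseROI((2.0, -1.5), (0.5, 0.5), role="mass")
TISSUE = EllipseROI((2.0, 0.5), (0.5, 0.5), role="tissue")


class TestRoiMask:
    def test_tiny_circle_contains_pixels(self):
        roi = EllipseROI((2.0, 0.0), (0.05, 0.15), role="mass")
        mask = roi_mask(roi, GEOM, SHAPE)
        assert mask.sum() >= 1

    def test_roi_outside_image_raises(self):
        roi = EllipseROI((50.0, 0.0), (0.5, 0.5), role="mass")
        with pytest.raises(ValueError, match="no pixels"):
            roi_mask(roi, GEOM, SHAPE)

    def test_clipped_mask_matches_per_pixel_oracle(self):
        roi = EllipseROI((0.2, -3.0), (0.7, 1.1), role="mass")  # hangs off two edges
        mask = roi_mask(roi, GEOM, SHAPE)
        depth = GEOM.sample_depth_mm(np.arange(SHAPE[0]))
        lateral = GEOM.line_positions_mm()
        for r in range(0, SHAPE[0], 7):
            for c in range(0, SHAPE[1], 5):
                inside = ((depth[r] - 0.2) / 0.7) ** 2 + ((lateral[c] + 3.0) / 1.1) ** 2 <= 1
                assert mask[r, c] == inside

    def test_pair_validation_accepts_lateral_rule(self):
        validate_roi_pair(MASS, TISSUE)  # nearest-edge gap 1.0 mm

    def test_pair_validation_rejects_mismatched_size(self):
        bad = EllipseROI((2.0, 0.5), (0.4, 0.5), role="tissue")
        with pytest.raises(ValueError, match="same semi-axes"):
            validate_roi_pair(MASS, bad)

    def test_pair_validation_rejects_touching_rois(self):
        bad = EllipseROI((2.0, -0.7), (0.5, 0.5), role="tissue")  # gap -0.2 mm
        with pytest.raises(ValueError, match="pairing"):
            validate_roi_pair(MASS, bad)

    def test_pair_validation_depth_fallback(self):
        below = EllipseROI((3.5, -1.5), (0.5, 0.5), role="tissue")  # 0.5 mm edge gap
        validate_roi_pair(MASS, below)


class TestContrast:
    def test_equal_means_zero_db(self):
        img = two_level_image(1.0, 1.0, MASS)
        assert contrast(img, MASS, TISSUE) == pytest.approx(0.0)

    def test_tenth_ratio_minus_twenty_db(self):
        img = two_level_image(0.1, 1.0, MASS)
        assert contrast(img, MASS, TISSUE) == pytest.approx(-20.0)

    def test_scale_invariance(self):
        img = two_level_image(0.3, 1.0, MASS, noise=0.01, seed=4)
        scaled = image_from(7.7 * img.values)
        assert contrast(scaled, MASS, TISSUE) == pytest.approx(contrast(img, MASS, TISSUE))

    def test_zero_tissue_mean_raises(self):
        img = two_level_image(1.0, 0.0, MASS)
        with pytest.raises(ValueError, match="tissue"):
            contrast(img, MASS, TISSUE)

    def test_zero_mass_mean_is_below_floor_sentinel(self):
        img = two_level_image(0.0, 1.0, MASS)
        assert contrast(img, MASS, TISSUE) == -np.inf

    def test_linear_das_image_rejected(self):
        img = image_from(np.ones(SHAPE), mode="DAS")
        with pytest.raises(ValueError, match="envelope"):
            contrast(img, MASS, TISSUE)

    def test_reads_retained_linear_values_after_log_compression(self):
        from slscbf.beamform import display_process

        img = two_level_image(0.1, 1.0, MASS)
        compressed = display_process(img)
        assert contrast(compressed, MASS, TISSUE) == pytest.approx(-20.0)


class TestContrastDifference:
    def test_identical_contrasts_give_zero(self):
        img = two_level_image(0.5, 1.0, MASS)
        assert contrast_difference(img, img, MASS, TISSUE) == pytest.approx(0.0)

    def test_sign_convention(self):
        bmode = two_level_image(0.1, 1.0, MASS)  # -20 dB
        coh = two_level_image(0.01, 1.0, MASS)  # -40 dB
        assert contrast_difference(bmode, coh, MASS, TISSUE) == pytest.approx(20.0)

    def test_antisymmetric_under_role_swap(self):
        a = two_level_image(0.2, 1.0, MASS, noise=0.01, seed=1)
        b = two_level_image(0.4, 1.0, MASS, noise=0.01, seed=2)
        assert contrast_difference(a, b, MASS, TISSUE) == pytest.approx(
            -contrast_difference(b, a, MASS, TISSUE)
        )

    def test_band_mismatch_raises(self):
        a = two_level_image(0.2, 1.0, MASS)
        b = image_from(two_level_image(0.4, 1.0, MASS).values, band="harmonic")
        with pytest.raises(ValueError, match="band"):
            contrast_difference(a, b, MASS, TISSUE)


class TestLagOneCoherence:
    def test_identical_channels_give_unit_map(self):
        g = AcquisitionGeometry(n_receive_elements=4, n_scan_lines=2)
        sig = np.sin(np.linspace(0.1, 8, 30))
        samples = np.tile(sig[:, None, None], (1, 4, 2))
        frame = ChannelDataFrame(samples, g, "fundamental", delays_applied=True)
        loc = lag_one_coherence_map(frame, kernel_length=5)
        np.testing.assert_allclose(loc.values, 1.0, atol=1e-9)

    def test_independent_noise_mean_near_zero(self):
        rng = np.random.default_rng(6)
        g = AcquisitionGeometry(n_receive_elements=8, n_scan_lines=4)
        vals = []
        for _ in range(40):
            frame = ChannelDataFrame(
                rng.standard_normal((40, 8, 4)), g, "fundamental", delays_applied=True
            )
            vals.append(lag_one_coherence_map(frame, kernel_length=5).values.mean())
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 0.01

    def test_equals_stack_lag_one(self, toy_frame):
        from slscbf.beamform import coherence_stack

        loc = lag_one_coherence_map(toy_frame, kernel_length=3)
        stack = coherence_stack(toy_frame, M=3, kernel_length=3)
        np.testing.assert_array_equal(loc.values, stack.lag_images[:, :, 0])

    def test_negative_values_retained(self):
        g = AcquisitionGeometry(n_receive_elements=2, n_scan_lines=1)
        samples = np.zeros((20, 2, 1))
        samples[:, 0, 0] = np.sin(np.arange(20))
        samples[:, 1, 0] = -np.sin(np.arange(20))
        frame = ChannelDataFrame(samples, g, "fundamental", delays_applied=True)
        loc = lag_one_coherence_map(frame, kernel_length=5)
        assert loc.values.min() < -0.99

    def test_mean_loc_constant_map(self):
        img = image_from(np.full(SHAPE, 0.37), mode="LOC")
        assert mean_loc(img, MASS) == pytest.approx(0.37)

    def test_mean_loc_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(-1, 1, SHAPE)
        img = image_from(values, mode="LOC")
        mask = roi_mask(MASS, GEOM, SHAPE)
        total = count = 0
        for r in range(SHAPE[0]):
            for c in range(SHAPE[1]):
                if mask[r, c]:
                    total += values[r, c]
                    count += 1
        assert mean_loc(img, MASS) == pytest.approx(total / count)


class TestBinCount:
    def test_standard_normal_pool_in_printed_band(self):
        rng = np.random.default_rng(123)
        x = rng.standard_normal(1000)
        n = select_bin_count(x[:500], x[500:])
        assert 19 <= n <= 304

    def test_constant_pool_clamps_to_two(self):
        assert select_bin_count(np.ones(50), np.ones(50)) == 2

    def test_bin_count_grows_smoothly_with_sample_size(self):
        rng = np.random.default_rng(5)
        counts = []
        for n in (500, 1000, 2000, 4000):
            x = rng.standard_normal(n)
            counts.append(select_bin_count(x[: n // 2], x[n // 2 :]))
        ratios = [b / a for a, b in zip(counts, counts[1:])]
        assert all(0.9 <= r <= 2.0 for r in ratios)  # ~n^(1/3) growth, no jumps

    def test_requires_two_samples_per_roi(self):
        with pytest.raises(ValueError, match="2 samples"):
            select_bin_count(np.array([1.0]), np.ones(10))


class TestGcnr:
    def test_identical_rois_zero(self):
        rng = np.random.default_rng(0)
        values = np.tile(rng.uniform(0, 1, SHAPE[0])[:, None], (1, SHAPE[1]))
        img = image_from(values)
        mirrored = EllipseROI(TISSUE.center_mm, TISSUE.semi_axes_mm, role="tissue")
        shifted_mass = EllipseROI((2.0, -0.5), (0.5, 0.5), role="mass")
        # identical depth profile in both ROIs -> identical histograms
        assert gcnr(img, shifted_mass, mirrored) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        img = two_level_image(10.0, 1.0, MASS, noise=0.05, seed=2)
        assert gcnr(img, MASS, TISSUE) == pytest.approx(1.0)

    def test_half_overlapping_uniforms(self):
        # analytic overlap of U(0,1) and U(0.5,1.5) is 0.5 -> gCNR 0.5
        rng = np.random.default_rng(9)
        values = np.zeros(SHAPE)
        mmask = roi_mask(MASS, GEOM, SHAPE)
        tmask = roi_mask(TISSUE, GEOM, SHAPE)
        values[mmask] = rng.uniform(0.0, 1.0, mmask.sum())
        values[tmask] = rng.uniform(0.5, 1.5, tmask.sum())
        img = image_from(values)
        assert gcnr(img, MASS, TISSUE) == pytest.approx(0.5, abs=0.08)

    def test_scale_invariance(self):
        img = two_level_image(0.4, 1.0, MASS, noise=0.2, seed=7)
        scaled = image_from(13.0 * img.values)
        assert gcnr(scaled, MASS, TISSUE) == pytest.approx(gcnr(img, MASS, TISSUE), abs=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(10)
        for seed in range(5):
            img = image_from(np.random.default_rng(seed).uniform(0, 1, SHAPE))
            assert 0.0 <= gcnr(img, MASS, TISSUE) <= 1.0


class TestClassification:
    def test_loc_thresholds(self):
        assert classify_mass(mean_loc_value=0.10)["loc"] == "fluid"
        assert classify_mass(mean_loc_value=0.50)["loc"] == "solid"
        assert classify_mass(mean_loc_value=0.28)["loc"] == "solid"  # tie -> solid

    def test_contrast_difference_sign(self):
        assert classify_mass(contrast_difference_db=-5.0)["contrast_difference"] == "solid"
        assert classify_mass(contrast_difference_db=5.0)["contrast_difference"] == "fluid"
        assert classify_mass(contrast_difference_db=0.0)["contrast_difference"] == "solid"

    def test_gcnr_threshold_and_tie(self):
        assert classify_mass(gcnr_value=0.9)["gcnr"] == "fluid"
        assert classify_mass(gcnr_value=0.5)["gcnr"] == "solid"
        assert classify_mass(gcnr_value=0.73)["gcnr"] == "solid"

    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(7, 0, 25, 3), (1.0, 25 / 28)),
            (ConfusionCounts(7, 0, 24, 4), (1.0, 24 / 28)),
            (ConfusionCounts(7, 0, 27, 1), (1.0, 27 / 28)),
        ],
    )
    def test_sensitivity_specificity_values(self, counts, expected):
        perf = sensitivity_specificity(counts)
        assert perf.sensitivity == pytest.approx(expected[0])
        assert perf.specificity == pytest.approx(expected[1])

    def test_undefined_statistics_flagged(self):
        perf = sensitivity_specificity(ConfusionCounts(0, 0, 0, 0))
        assert perf.sensitivity is None and perf.specificity is None
        assert not perf.defined

    def test_confusion_from_labels_skips_mixed(self):
        pairs = [
            ("fluid", "fluid"),
            ("fluid", "solid"),
            ("solid", "solid"),
            ("solid", "fluid"),
            ("mixed", "fluid"),
        ]
        counts = confusion_from_labels(pairs)
        assert (counts.TP, counts.FN, counts.TN, counts.FP) == (1, 1, 1, 1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1)


class TestHarmonicRatioMap:
    def make_env(self, values, band):
        return BeamformedImage(values, "DAS", band, "envelope", GEOM)

    def test_half_amplitude_quantizes_to_six_db(self):
        fund = self.make_env(np.full(SHAPE, 2.0), "fundamental")
        harm = self.make_env(np.full(SHAPE, 1.0), "harmonic")
        qmap, mean_red = harmonic_ratio_map(fund, harm, kernel=(9, 3))
        assert mean_red == pytest.approx(20 * np.log10(2), abs=1e-9)
        np.testing.assert_allclose(qmap, 6.0)

    def test_equal_images_zero_reduction(self):
        fund = self.make_env(np.full(SHAPE, 1.5), "fundamental")
        harm = self.make_env(np.full(SHAPE, 1.5), "harmonic")
        qmap, mean_red = harmonic_ratio_map(fund, harm, kernel=(9, 3))
        assert mean_red == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(qmap, 0.0)

    def test_shape_mismatch_raises(self):
        fund = self.make_env(np.ones(SHAPE), "fundamental")
        g2 = dataclasses.replace(GEOM, n_scan_lines=32)
        harm = BeamformedImage(np.ones((SHAPE[0], 32)), "DAS", "harmonic", "envelope", g2)
        with pytest.raises(ValueError, match="shape"):
            harmonic_ratio_map(fund, harm)
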