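import numpy as np
import pytest

from srslipid.io_stacks import LipidDroplet
from srslipid.ld_segmentation import label_components_3d, measure_lds
from srslipid.unsaturation import (
    attach_unsaturation,
    average_unsaturation,
    compute_ratio_map,
    fit_calibration,
    hyperstack_peak_height,
    weighted_unsaturation,
)
from srslipid.io_stacks import HyperStack

from conftest import make_stack


class TestComputeRatioMap:
    def test_proportional_channels_constant_ratio(self):
        rng = np.random.default_rng(1)
        denom = rng.uniform(1.0, 2.0, (4, 8, 8))
        ratio = compute_ratio_map(make_stack(0.3 * denom, 3010.0), make_stack(denom), 0.5)
        assert ratio.valid_mask.all()
        np.testing.assert_allclose(ratio.ratios, 0.3, rtol=1e-12)

    def test_depth_profile_cancels_exactly(self):
        # multiplying both channels by exp(-z/L) leaves the ratio untouched
        rng = np.random.default_rng(2)
        denom = rng.uniform(1.0, 2.0, (6, 5, 5))
        numer = rng.uniform(0.1, 0.5, (6, 5, 5)) * denom
        f = np.exp(-np.arange(6) / 3.0)[:, None, None]
        r_plain = compute_ratio_map(make_stack(numer, 3010.0), make_stack(denom), 0.0)
        r_atten = compute_ratio_map(
            make_stack(numer * f, 3010.0), make_stack(denom * f), 0.0
        )
        common = r_plain.valid_mask & r_atten.valid_mask
        # identical up to float rounding of the two divisions
        np.testing.assert_allclose(
            r_plain.ratios[common], r_atten.ratios[common], rtol=1e-14
        )

    def test_zero_denominator_invalid_and_finite(self):
        denom = np.zeros((2, 3, 3))
        denom[0, 0, 0] = 2.0
        ratio = compute_ratio_map(make_stack(np.ones((2, 3, 3)), 3010.0), make_stack(denom), 0.5)
        assert ratio.valid_mask.sum() == 1
        assert np.isfinite(ratio.ratios).all()
        assert (ratio.ratios >= 0).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_ratio_map(
                make_stack(np.ones((2, 3, 3)), 3010.0), make_stack(np.ones((2, 4, 4))), 0.0
            )


class TestAttachUnsaturation:
    def _one_droplet_setup(self, value=0.25):
        labels = np.zeros((3, 5, 5), dtype=np.int32)
        labels[1, 1:4, 1:4] = 1
        denom = np.where(labels > 0, 2.0, 0.1)
        numer = value * denom
        ratio = compute_ratio_map(make_stack(numer, 3010.0), make_stack(denom), 0.5)
        droplets = measure_lds(labels, make_stack(denom).geometry)
        return droplets, labels, ratio, numer, denom

    def test_uniform_ratio_recovered(self):
        droplets, labels, ratio, _, _ = self._one_droplet_setup(0.25)
        (d,) = attach_unsaturation(droplets, labels, ratio)
        assert d.mean_unsaturation == pytest.approx(0.25)

    def test_summed_mode_matches_on_uniform_droplet(self):
        droplets, labels, ratio, numer, denom = self._one_droplet_setup(0.4)
        (d,) = attach_unsaturation(
            droplets, labels, ratio, mode="summed", numerator=numer, denominator=denom
        )
        assert d.mean_unsaturation == pytest.approx(0.4)

    def test_background_corrected_mode_on_uniform_droplet(self):
        droplets, labels, ratio, numer, denom = self._one_droplet_setup(0.35)
        (d,) = attach_unsaturation(
            droplets,
            labels,
            ratio,
            mode="background_corrected",
            numerator=numer,
            denominator=denom,
        )
        assert d.mean_unsaturation == pytest.approx(0.35, rel=1e-6)

    def test_no_valid_voxels_left_unmeasured(self):
        droplets, labels, _, numer, denom = self._one_droplet_setup()
        ratio = compute_ratio_map(make_stack(numer, 3010.0), make_stack(denom), 10.0)
        (d,) = attach_unsaturation(droplets, labels, ratio)
        assert d.mean_unsaturation is None
        with pytest.raises(ValueError):
            average_unsaturation([d])

    def test_unknown_mode_rejected(self):
        droplets, labels, ratio, _, _ = self._one_droplet_setup()
        with pytest.raises(ValueError):
            attach_unsaturation(droplets, labels, ratio, mode="median")


def _d(volume, unsat, label=1):
    return LipidDroplet(label, 1, volume, (0.0, 0.0, 0.0), unsat)


class TestSummaries:
    def test_average_unsaturation(self):
        assert average_unsaturation([_d(1, 0.2, 1), _d(1, 0.4, 2)]) == pytest.approx(0.3)
        assert average_unsaturation([_d(1, 0.5)]) == 0.5

    def test_weighted_unsaturation_example(self):
        uw = weighted_unsaturation([_d(1.0, 0.2, 1), _d(3.0, 0.4, 2)])
        assert uw == pytest.approx(0.35)

    def test_equal_volumes_weighted_equals_unweighted(self):
        ds = [_d(2.0, u, i + 1) for i, u in enumerate([0.1, 0.3, 0.6])]
        assert weighted_unsaturation(ds) == pytest.approx(average_unsaturation(ds))

    def test_weighted_lies_in_convex_hull(self):
        rng = np.random.default_rng(8)
        ds = [
            _d(v, u, i + 1)
            for i, (v, u) in enumerate(zip(rng.uniform(0.5, 9, 30), rng.uniform(0.1, 0.6, 30)))
        ]
        uw = weighted_unsaturation(ds)
        us = [d.mean_unsaturation for d in ds]
        assert min(us) <= uw <= max(us)

    def test_anticorrelated_sizes_pull_weighted_below_mean(self):
        # big droplets made less unsaturated: volume weighting must drop U_w
        ds = [_d(v, 0.6 - 0.05 * v, i + 1) for i, v in enumerate([1, 2, 4, 8])]
        assert weighted_unsaturation(ds) < average_unsaturation(ds)

    def test_no_droplets_raises(self):
        with pytest.raises(ValueError):
            weighted_unsaturation([])


class TestFitCalibration:
    def test_exact_line(self):
        model = fit_calibration([0, 1, 2], [0.05, 0.15, 0.25])
        assert model.slope == pytest.approx(0.10, rel=1e-12)
        assert model.intercept == pytest.approx(0.05, rel=1e-12)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_line_slope_within_3_se(self):
        rng = np.random.default_rng(12)
        cc = np.arange(7)
        ratios = 0.1 * cc + 0.05 + rng.normal(0, 0.01, 7)
        model = fit_calibration(cc, ratios)
        # standard error of the OLS slope with sigma=0.01 on x = 0..6
        se = 0.01 / np.sqrt(np.sum((cc - cc.mean()) ** 2))
        assert abs(model.slope - 0.1) < 3 * se

    def test_identical_cc_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([2, 2, 2], [0.1, 0.2, 0.3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([0, 1], [0.1, 0.2])


class TestHyperstackPeakHeight:
    def _hstack(self, spectra):
        """spectra: callable wn -> (z,y,x) array."""
        wns = np.arange(2800.0, 3051.0, 5.0)
        frames = [make_stack(spectra(wn), wn) for wn in wns]
        return HyperStack(frames)

    def test_flat_spectrum_gives_zero(self):
        h = self._hstack(lambda wn: np.full((2, 3, 3), 1.7))
        height = hyperstack_peak_height(h, 3010.0, (2800.0, 2830.0))
        np.testing.assert_allclose(height, 0.0, atol=1e-12)

    def test_gaussian_peak_height_recovered(self):
        amp, center, width = 2.0, 3010.0, 12.0
        h = self._hstack(
            lambda wn: np.full((2, 3, 3), amp * np.exp(-0.5 * ((wn - center) / width) ** 2))
        )
        height = hyperstack_peak_height(h, center, (2800.0, 2830.0))
        # 5 cm⁻¹ sampling: nearest frame sits exactly on the peak here;
        # the baseline band carries a tiny tail of the peak
        assert np.allclose(height, amp, rtol=0.02)

    def test_center_outside_range_raises(self):
        h = self._hstack(lambda wn: np.ones((2, 3, 3)))
        with pytest.raises(ValueError):
            hyperstack_peak_height(h, 2700.0, (2800.0, 2830.0))

    def test_empty_baseline_band_raises(self):
        h = self._hstack(lambda wn: np.ones((2, 3, 3)))
        with pytest.raises(ValueError):
            hyperstack_peak_height(h, 2900.0, (2701.0, 2702.0))
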