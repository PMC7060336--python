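"""Tests of ADC computation and the DSC -> leakage-corrected nCBV chain."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid
from scipy.stats import spearmanr

from gliorad.grids import DscSeries, DwiPair, ImageVolume, NawmRoiSpec
from gliorad.param_maps import (
    compute_adc,
    compute_cbv,
    dsc_to_ncbv,
    fit_leakage,
    normalize_cbv,
    signal_to_delta_r2star,
)
from gliorad.synthetic import gamma_variate_bolus, generate_dsc_series


def _pair(s0, sb, b=1000.0):
    shape = (2, 2, 2)
    return DwiPair(ImageVolume(np.full(shape, s0)), ImageVolume(np.full(shape, sb)), b)


class TestAdc:
    def test_closed_form_decay(self):
        adc = compute_adc(_pair(1000.0, 1000.0 * np.exp(-1.0)))
        assert adc.data == pytest.approx(1.0e-3)

    def test_equal_signals_zero_adc(self):
        assert compute_adc(_pair(800.0, 800.0)).data == pytest.approx(0.0)

    def test_known_exponent(self):
        adc = compute_adc(_pair(800.0, 800.0 * np.exp(-0.7)))
        assert adc.data == pytest.approx(0.7e-3)

    def test_nonpositive_signal_invalidated(self):
        s0 = np.full((2, 2, 2), 1000.0)
        sb = np.full((2, 2, 2), 500.0)
        sb[0, 0, 0] = -1.0
        adc = compute_adc(DwiPair(ImageVolume(s0), ImageVolume(sb), 1000.0))
        assert not adc.valid[0, 0, 0]
        assert adc.valid.sum() == 7

    def test_all_invalid_errors(self):
        with pytest.raises(ValueError, match="non-positive"):
            compute_adc(_pair(-1.0, -1.0))

    def test_pointwise_permutation_equivariance(self, rng):
        s0 = rng.uniform(500, 1500, (3, 3, 3))
        sb = s0 * np.exp(-rng.uniform(0.2, 1.0, (3, 3, 3)))
        adc = compute_adc(DwiPair(ImageVolume(s0), ImageVolume(sb), 1000.0)).data
        perm = rng.permutation(27)
        adc_perm = compute_adc(DwiPair(
            ImageVolume(s0.ravel()[perm].reshape(3, 3, 3)),
            ImageVolume(sb.ravel()[perm].reshape(3, 3, 3)), 1000.0)).data
        np.testing.assert_allclose(adc_perm.ravel(), adc.ravel()[perm])


class TestDeltaR2star:
    def test_flat_signal_zero_curve(self):
        sig = np.full((2, 2, 2, 30), 400.0)
        series = DscSeries(sig, te_s=0.04, tr_s=1.8, baseline_index_range=(0, 5))
        curves, valid = signal_to_delta_r2star(series)
        assert valid.all()
        np.testing.assert_allclose(curves, 0.0)

    def test_exponential_drop_inverts_exactly(self):
        x = 7.5
        sig = np.full((1, 1, 1, 30), 400.0)
        sig[..., 10:] = 400.0 * np.exp(-0.04 * x)
        series = DscSeries(sig, 0.04, 1.8, (0, 5))
        curves, _ = signal_to_delta_r2star(series)
        np.testing.assert_allclose(curves[0, 0, 0, 10:], x, rtol=1e-12)

    def test_round_trip_from_generator(self):
        cbv = np.array([[[0.5, 1.0, 2.5]]])
        k2 = np.array([[[0.0, 0.05, 0.1]]])
        series = generate_dsc_series(cbv, k2, 0.04, 1.8, 50, 8, 0.0, seed=0)
        curves, valid = signal_to_delta_r2star(series)
        c = gamma_variate_bolus(50, 1.8, 8)
        cint = cumulative_trapezoid(c, dx=1.8, initial=0.0)
        expected = cbv[..., None] * c - k2[..., None] * cint
        assert valid.all()
        np.testing.assert_allclose(curves, expected, atol=1e-10)


class TestLeakage:
    @pytest.fixture()
    def reference_setup(self):
        c = gamma_variate_bolus(50, 1.8, 8)
        ref_field = np.ones((4, 4, 4, 1)) * c  # uniform non-leaky tissue
        return c, ref_field

    def test_scaled_reference_recovers_k1_and_zero_k2(self, reference_setup):
        c, curves = reference_setup
        curves = curves.copy()
        curves[0, 0, 0] = 2.0 * c
        nonenh = np.ones((4, 4, 4), bool)
        nonenh[0, 0, 0] = False
        fit, corrected = fit_leakage(curves, nonenh, tr_s=1.8)
        assert fit.k1[0, 0, 0] == pytest.approx(2.0, abs=1e-10)
        assert fit.k2[0, 0, 0] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(corrected[0, 0, 0], curves[0, 0, 0], atol=1e-10)

    def test_linear_model_recovered_exactly(self, reference_setup):
        c, curves = reference_setup
        curves = curves.copy()
        cint = cumulative_trapezoid(c, dx=1.8, initial=0.0)
        k1, k2 = 1.7, 0.31
        curves[1, 1, 1] = k1 * c - k2 * cint
        nonenh = np.ones((4, 4, 4), bool)
        nonenh[1, 1, 1] = False
        fit, corrected = fit_leakage(curves, nonenh, tr_s=1.8)
        assert fit.k1[1, 1, 1] == pytest.approx(k1, abs=1e-9)
        assert fit.k2[1, 1, 1] == pytest.approx(k2, abs=1e-9)
        # corrected curve restores the leakage term: k1 * ref
        np.testing.assert_allclose(corrected[1, 1, 1], k1 * c, atol=1e-9)

    def test_corrected_integral_scales_with_k1(self, reference_setup):
        c, curves = reference_setup
        cint = cumulative_trapezoid(c, dx=1.8, initial=0.0)
        curves = curves.copy()
        curves[2, 2, 2] = 3.0 * c - 0.2 * cint
        nonenh = np.ones((4, 4, 4), bool)
        nonenh[2, 2, 2] = False
        fit, corrected = fit_leakage(curves, nonenh, tr_s=1.8)
        total_vox = np.trapezoid(corrected[2, 2, 2], dx=1.8)
        total_ref = np.trapezoid(fit.reference_curve, dx=1.8)
        assert total_vox == pytest.approx(3.0 * total_ref, rel=1e-9)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            fit_leakage(np.zeros((2, 2, 2, 30)), np.ones((2, 2, 2), bool), 1.8)


class TestCbv:
    def test_zero_curve_zero_cbv(self):
        cbv = compute_cbv(np.zeros((2, 2, 2, 30)), 1.8, (0, 5))
        np.testing.assert_allclose(cbv.data, 0.0)

    def test_triangle_integral(self):
        curves = np.zeros((1, 1, 1, 20))
        # triangle: rise over 4 steps to height 6, fall over 4 steps
        curves[0, 0, 0, 5:14] = np.concatenate([np.linspace(0, 6, 5), np.linspace(6, 0, 5)[1:]])
        cbv = compute_cbv(curves, tr_s=1.0, baseline_index_range=(0, 5))
        assert cbv.data[0, 0, 0] == pytest.approx(6.0 * 8.0 / 2.0)

    def test_negative_integral_clipped(self):
        curves = np.full((1, 1, 1, 20), -1.0)
        cbv = compute_cbv(curves, 1.0, (0, 5))
        assert cbv.data[0, 0, 0] == 0.0

    def test_window_outside_series_rejected(self):
        with pytest.raises(ValueError):
            compute_cbv(np.zeros((1, 1, 1, 10)), 1.0, (0, 10))


class TestNormalizeCbv:
    def _cbv(self, data):
        return ImageVolume(np.asarray(data, float))

    def test_roi_mean_maps_to_one(self):
        data = np.full((9, 9, 9), 5.0)
        data[6, 6, 6] = 7.5
        roi = NawmRoiSpec(center_mm=(2.0, 2.0, 2.0), diameter_mm=4.0)
        ncbv = normalize_cbv(self._cbv(data), roi)
        assert ncbv.data[2, 2, 2] == pytest.approx(1.0)
        assert ncbv.data[6, 6, 6] == pytest.approx(1.5)

    def test_global_scale_invariance(self, rng):
        data = rng.uniform(1.0, 4.0, (9, 9, 9))
        roi = NawmRoiSpec((4.0, 4.0, 4.0))
        a = normalize_cbv(self._cbv(data), roi).data
        b = normalize_cbv(self._cbv(data * 17.3), roi).data
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_roi_overlapping_tumor_rejected(self):
        tumor = np.zeros((9, 9, 9))
        tumor[4, 4, 4] = 1.0
        with pytest.raises(ValueError, match="overlaps"):
            normalize_cbv(self._cbv(np.ones((9, 9, 9))),
                          NawmRoiSpec((4.0, 4.0, 4.0)), tumor_mask=tumor)


class TestEndToEndRecovery:
    def test_noise_free_ncbv_tracks_truth(self, phantom_subject):
        """Noise-free DSC pipeline recovers the generating CBV up to scale."""
        from gliorad.synthetic import generate_dsc_series

        subj = phantom_subject
        truth = subj.truth
        series = generate_dsc_series(truth.true_cbv_map, truth.true_k2,
                                     0.04, 1.8, 60, 8, 0.0, seed=0,
                                     spacing=subj.mask.spacing)
        nawm_idx = np.argwhere(subj.nawm_mask)
        center = tuple(nawm_idx.mean(axis=0))
        ncbv, fit = dsc_to_ncbv(series, subj.brain_mask, subj.mask.data,
                                NawmRoiSpec(center))
        brain = subj.brain_mask & ncbv.valid_mask()
        x = truth.true_cbv_map[brain]
        y = ncbv.data[brain]
        # regression through origin: recovered = scale * truth
        scale = (x @ y) / (x @ x)
        ss_res = np.sum((y - scale * x) ** 2)
        ss_tot = np.sum(y**2)
        assert 1.0 - ss_res / ss_tot > 0.999
        rho = spearmanr(x, y).statistic
        assert rho > 0.999

    def test_zero_k2_correction_is_identity(self):
        cbv = np.random.default_rng(0).uniform(0.5, 3.0, (5, 5, 5))
        series = generate_dsc_series(cbv, np.zeros_like(cbv), 0.04, 1.8, 50, 8,
                                     0.0, seed=0)
        curves, _ = signal_to_delta_r2star(series)
        nonenh = np.ones((5, 5, 5), bool)
        fit, corrected = fit_leakage(curves, nonenh, 1.8)
        np.testing.assert_allclose(corrected, curves, atol=1e-8)
        np.testing.assert_allclose(fit.k2, 0.0, atol=1e-8)
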