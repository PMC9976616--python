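"""Contrast-chain operations: dark/detrend, log-mean, spectroscopy, GSR, QC."""

import numpy as np
import pytest

from woi import io_mask_atlas as io
from woi import preprocess as pp
from woi import synthetic_fixtures as sf


def stack_of(data, rate=16.8, wl=530):
    return io.RawStack(np.asarray(data, float), rate, wl)


class TestDarkAndDetrend:
    def test_constant_minus_dark(self):
        out = pp.subtract_dark(stack_of(np.full((3, 3, 4), 100.0)),
                               np.full((3, 3), 10.0))
        assert np.all(out.data == 90.0)

    def test_clipping_at_zero(self):
        out = pp.subtract_dark(stack_of(np.full((2, 2, 2), 5.0)),
                               np.full((2, 2), 8.0))
        assert np.all(out.data == 0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pp.subtract_dark(stack_of(np.ones((2, 2, 2))), np.ones((3, 3)))

    def test_temporal_ramp_removed(self):
        t = np.arange(10.0)
        movie = np.ones((4, 4, 1)) * (2 + 3 * t)
        out = pp.detrend_spatiotemporal(stack_of(movie))
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_spatial_plane_removed_single_frame(self):
        rr = np.mgrid[0:6, 0:6][0].astype(float)
        assert np.allclose(pp.detrend_spatial(2 + rr), 0.0, atol=1e-10)

    def test_sinusoid_survives_temporal_detrend(self):
        t = np.arange(200.0)
        wave = np.sin(2 * np.pi * t / 40)
        movie = np.ones((4, 4, 1)) * (5 + 0.01 * t + wave)
        out = pp.detrend_temporal(movie)
        slope = np.polyfit(t, out[0, 0], 1)[0]
        assert abs(slope) < 1e-8
        # sinusoid largely retained (a finite window projects slightly onto a line)
        assert np.corrcoef(out[0, 0], wave)[0, 1] > 0.98
        assert np.ptp(out[0, 0]) == pytest.approx(np.ptp(wave), rel=0.15)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            pp.detrend_temporal(np.ones((2, 2, 2)))


class TestLogmeanAndNormalize:
    def test_constant_trace_maps_to_zero(self):
        out = pp.logmean(np.full((1, 1, 3), 5.0))
        assert np.allclose(out, 0.0)

    def test_two_sample_values(self):
        out = pp.logmean(np.array([[[2.0, 1.0]]]))
        assert out[0, 0] == pytest.approx([0.28768, -0.40546], abs=1e-5)

    def test_zero_sample_rejected_unless_floored(self):
        movie = np.array([[[0.0, 2.0]]])
        with pytest.raises(ValueError, match="non-positive"):
            pp.logmean(movie)
        out = pp.logmean(movie, eps_floor=1e-6)
        assert np.isfinite(out).all()

    def test_mean_normalize_examples(self, rng):
        assert np.allclose(pp.mean_normalize(np.full((2, 2, 4), 7.0)), 1.0)
        out = pp.mean_normalize(np.array([[[2.0, 1.0]]]))
        assert out[0, 0] == pytest.approx([4 / 3, 2 / 3])
        movie = rng.uniform(1, 5, (4, 4, 50))
        assert np.allclose(pp.mean_normalize(movie).mean(axis=-1), 1.0,
                           atol=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            pp.mean_normalize(np.full((1, 1, 3), -1.0))


class TestSpectroscopyModel:
    def test_delta_like_led_recovers_pointwise_extinction(self, spectra):
        ext, _ = spectra
        import pandas as pd
        lam0 = 560.0
        grid = np.array([lam0 - 0.2, lam0, lam0 + 0.2])
        led = pd.DataFrame({"wavelength_nm": grid,
                            "relative_intensity": [0.0, 1.0, 0.0]})
        m = pp.build_spectroscopy_model(ext, {560: led, 600: led.assign(
            wavelength_nm=grid + 40)}, excitation_nm=None)
        eps0 = [np.interp(lam0, ext.wavelength_nm, ext[c])
                for c in ("eps_hbo2", "eps_hb")]
        assert np.allclose(m.E[0], eps0, rtol=1e-3)

    def test_full_rank_with_distinct_leds(self, model):
        assert np.linalg.matrix_rank(model.E) == 2
        assert model.condition_number < 1e3

    def test_led_outside_extinction_grid_rejected(self, spectra):
        ext, _ = spectra
        import pandas as pd
        led = pd.DataFrame({"wavelength_nm": [900.0, 910.0, 920.0],
                            "relative_intensity": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="overlap"):
            pp.build_spectroscopy_model(ext, {900: led, 910: led},
                                        excitation_nm=None)


class TestSolveSpectroscopy:
    def test_forward_inverse_identity(self, model, rng):
        dc = rng.normal(0, 1e-6, (2, 3, 4, 20))
        A = model.A
        y = np.einsum("ws,sxyt->wxyt", A, dc)
        hbo, hbr = pp.solve_spectroscopy([-y[i] for i in range(len(A))], model)
        assert np.linalg.norm(hbo - dc[0]) < 1e-10 * np.linalg.norm(dc[0])
        assert np.linalg.norm(hbr - dc[1]) < 1e-10 * np.linalg.norm(dc[1])

    def test_zero_maps_to_zero(self, model):
        zeros = [np.zeros((2, 2, 3))] * len(model.wavelengths)
        hbo, hbr = pp.solve_spectroscopy(zeros, model)
        assert not hbo.any() and not hbr.any()

    def test_noisy_overdetermined_equals_pseudoinverse(self, model, rng):
        y = rng.normal(size=(len(model.wavelengths), 3, 3, 10))
        hbo, hbr = pp.solve_spectroscopy(list(y), model)
        oracle = np.linalg.pinv(model.A) @ (-y.reshape(len(model.A), -1))
        assert np.array_equal(hbo.ravel(), oracle[0])
        assert np.array_equal(hbr.ravel(), oracle[1])

    def test_rank_deficient_rejected(self):
        m = pp.SpectroscopyModel((530, 531), np.array([[1.0, 2.0], [1.0, 2.0]]),
                                 np.ones(2))
        with pytest.raises(ValueError, match="rank deficient"):
            pp.solve_spectroscopy([np.ones((2, 2, 3))] * 2, m)


class TestHemoglobinCorrection:
    def test_zero_hemoglobin_is_identity(self, model, rng):
        fl = rng.uniform(0.5, 1.5, (3, 3, 5))
        z = np.zeros_like(fl)
        assert np.array_equal(
            pp.hemoglobin_correct_fluorescence(fl, z, z, model), fl)

    def test_forward_inverse_round_trip(self, model, rng):
        dhbo = rng.normal(0, 1e-6, (3, 3, 20))
        dhbr = -0.4 * dhbo
        atten = np.exp(-(model.eps_ex[0] * dhbo + model.eps_ex[1] * dhbr)
                       - (model.eps_em[0] * dhbo + model.eps_em[1] * dhbr))
        corrected = pp.hemoglobin_correct_fluorescence(
            2.0 * atten, dhbo, dhbr, model)
        assert np.allclose(corrected, 2.0, rtol=1e-8)

    def test_log_correction_linear_in_pathlength(self, model):
        hbo = np.full((1, 1, 2), 1e-6)
        hbr = np.zeros_like(hbo)
        one = np.ones_like(hbo)
        c1 = np.log(pp.hemoglobin_correct_fluorescence(one, hbo, hbr, model,
                                                       x_ex=1.0, x_em=1e-12))
        c2 = np.log(pp.hemoglobin_correct_fluorescence(one, hbo, hbr, model,
                                                       x_ex=2.0, x_em=1e-12))
        assert np.allclose(c2, 2 * c1)

    def test_missing_bands_rejected(self, model):
        bad = pp.SpectroscopyModel(model.wavelengths, model.E, model.L)
        with pytest.raises(ValueError):
            pp.hemoglobin_correct_fluorescence(np.ones((2, 2, 2)),
                                               np.zeros((2, 2, 2)),
                                               np.zeros((2, 2, 2)), bad)


class TestSmoothing:
    def test_constant_frame_unchanged(self):
        frame = np.full((12, 12), 3.5)
        assert np.allclose(pp.smooth_spatial(frame), 3.5)

    def test_impulse_peak_equals_kernel_peak(self):
        frame = np.zeros((21, 21))
        frame[10, 10] = 1.0
        out = pp.smooth_spatial(frame)
        assert out[10, 10] == pytest.approx(pp.gaussian_kernel()[2, 2])

    def test_zeros_stay_zero(self):
        assert not pp.smooth_spatial(np.zeros((8, 8, 3))).any()

    def test_masked_edges_do_not_bleed(self):
        mask = np.zeros((12, 12), bool)
        mask[3:9, 3:9] = True
        frame = np.where(mask, 2.0, 0.0)
        out = pp.smooth_spatial(frame, mask)
        assert np.allclose(out[mask], 2.0)


class TestGSR:
    def test_movie_equal_to_global_goes_to_zero(self, rng):
        g = rng.normal(size=30)
        movie = np.tile(g, (4, 4, 1))
        assert np.allclose(pp.global_signal_regress(movie), 0.0, atol=1e-12)

    def test_orthogonal_pixel_unchanged(self):
        nt = 40
        t = np.arange(nt)
        movie = np.zeros((2, 1, nt))
        movie[0, 0] = np.sin(2 * np.pi * t / 8)    # orthogonal to cos
        movie[1, 0] = -np.sin(2 * np.pi * t / 8) + np.cos(2 * np.pi * t / 8)
        out = pp.global_signal_regress(movie)
        # global signal is 0.5*cos; the sin component is untouched
        assert np.allclose(out[0, 0], movie[0, 0], atol=1e-10)

    def test_output_uncorrelated_with_global(self, rng):
        movie = rng.normal(size=(6, 6, 100))
        mask = np.ones((6, 6), bool)
        out = pp.global_signal_regress(movie, mask)
        g = movie[mask].mean(axis=0)
        corrs = [np.corrcoef(out[i, j], g)[0, 1]
                 for i in range(6) for j in range(6)]
        assert np.nanmax(np.abs(corrs)) < 1e-10

    def test_constant_global_signal_rejected(self):
        with pytest.raises(ValueError):
            pp.global_signal_regress(np.ones((3, 3, 10)))


class TestBandpassDownsample:
    def test_passband_sinusoid_preserved(self):
        rate, nt = 16.8, 2000
        t = np.arange(nt) / rate
        movie = np.sin(2 * np.pi * 1.0 * t)[None, None, :]
        out = pp.bandpass(movie, 0.4, 4.0, rate)[0, 0, 200:-200]
        amp = np.ptp(out) / 2
        assert 0.95 < amp < 1.05

    def test_slow_drift_attenuated(self):
        rate, nt = 16.8, 2000
        t = np.arange(nt) / rate
        movie = np.sin(2 * np.pi * 0.001 * t)[None, None, :]
        out = pp.bandpass(movie, 0.4, 4.0, rate)[0, 0, 200:-200]
        assert np.abs(out).max() < 0.05 * 1.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            pp.bandpass(np.ones((1, 1, 100)), 4.0, 0.4, 16.8)
        with pytest.raises(ValueError):
            pp.bandpass(np.ones((1, 1, 100)), 0.4, 10.0, 16.8)

    def test_double_filter_keeps_passband_attenuates_stopband(self):
        rate, nt = 16.8, 3000
        t = np.arange(nt) / rate
        passband = np.sin(2 * np.pi * 1.0 * t)[None, None, :]
        stop = np.sin(2 * np.pi * 0.2 * t)[None, None, :]
        once_p = pp.bandpass(passband, 0.4, 4.0, rate)
        twice_p = pp.bandpass(once_p, 0.4, 4.0, rate)
        amp = np.ptp(twice_p[0, 0, 300:-300]) / 2
        assert 0.9 < amp < 1.1
        once_s = np.abs(pp.bandpass(stop, 0.4, 4.0, rate)[0, 0, 300:-300]).max()
        twice_s = np.abs(pp.bandpass(pp.bandpass(stop, 0.4, 4.0, rate),
                                     0.4, 4.0, rate)[0, 0, 300:-300]).max()
        assert twice_s <= once_s * 1.01

    def test_downsample_shapes_and_values(self):
        movie = np.ones((156, 156, 8)) * 3.0
        out = pp.downsample(movie, 2, 2)
        assert out.shape == (78, 78, 4)
        assert np.allclose(out, 3.0)

    def test_downsample_block_mean(self):
        movie = np.arange(4.0).reshape(2, 2)[:, :, None] * np.ones((1, 1, 2))
        out = pp.downsample(movie, 2, 1)
        assert out.shape == (1, 1, 2)
        assert np.allclose(out, 1.5)

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            pp.downsample(np.ones((4, 4, 4)), 0, 1)


class TestMovementMetric:
    def test_constant_movie_zero_variance(self):
        qc = pp.movement_metric(np.full((4, 4, 10), 2.0))
        assert qc.global_var_deriv == 0.0
        assert qc.rms_deriv.shape == (9,)

    def test_global_jump_spikes_rms(self):
        movie = np.zeros((4, 4, 20))
        movie[:, :, 10:] = 5.0
        qc = pp.movement_metric(movie)
        assert np.argmax(qc.rms_deriv) == 9
        assert qc.rms_deriv[9] == pytest.approx(5.0)

    def test_white_noise_variance_scales_inverse_mask_size(self, rng):
        sigma = 0.7
        movie = rng.normal(0, sigma, (64, 64, 500))
        qc = pp.movement_metric(movie)
        expected = 2 * sigma ** 2 / (64 * 64)
        assert qc.global_var_deriv == pytest.approx(expected, rel=0.2)


class TestFullChain:
    def test_noiseless_beer_lambert_round_trip(self, model, full_mask):
        dhbo, dhbr = sf.default_hemo_waveforms((16, 16), 64)
        stacks, truth = sf.simulate_multiwavelength((dhbo, dhbr), model)
        cs = pp.process_stacks(list(stacks.values()), np.zeros((16, 16)),
                               full_mask, model,
                               detrend=False, smooth=False, gsr=False)
        for rec, name in ((cs.hbo, "dhbo"), (cs.hbr, "dhbr")):
            tru = truth[name] - truth[name].mean(axis=-1, keepdims=True)
            rel = np.linalg.norm(rec - tru) / np.linalg.norm(tru)
            assert rel < 0.01

    def test_contrasts_have_zero_temporal_mean(self, model, full_mask):
        dhbo, dhbr = sf.default_hemo_waveforms((16, 16), 64)
        stacks, _ = sf.simulate_multiwavelength((dhbo, dhbr), model)
        cs = pp.process_stacks(list(stacks.values()), np.zeros((16, 16)),
                               full_mask, model, smooth=False, gsr=False)
        for mv in cs.contrasts.values():
            assert np.abs(mv.mean(axis=-1)).max() < 1e-10

    def test_gsr_kills_global_variance(self, model, full_mask, rng):
        movie = rng.normal(size=(16, 16, 80)) + rng.normal(size=80)
        out = pp.global_signal_regress(movie, full_mask.mask)
        g_in = movie[full_mask.mask].mean(axis=0)
        g_out = out[full_mask.mask].mean(axis=0)
        assert np.var(g_out) <= 1e-20 * np.var(g_in) + 1e-25
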