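"""Voxelwise metric computations against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sps

import m3class as m3
from m3class.fmri_metrics import friston24


def toy_image(data, tr=2.0, mask=None):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return m3.TimeSeriesImage(data, tr, mask)


def sinusoid_image(freq_hz, amp=1.0, shape=(4, 4, 2), n_t=100, tr=2.0,
                   phase=0.0):
    t = np.arange(n_t) * tr
    sig = amp * np.sin(2 * np.pi * freq_hz * t + phase)
    data = np.broadcast_to(sig, shape + (n_t,)).copy()
    return toy_image(data, tr)


class TestNuisanceRegression:
    def test_friston24_expansion_structure(self, rng):
        p = rng.standard_normal((30, 6))
        x = friston24(p)
        assert x.shape == (30, 24)
        np.testing.assert_array_equal(x[:, :6], p)
        np.testing.assert_array_equal(x[:, 6:12], p**2)
        np.testing.assert_array_equal(x[1:, 12:18], p[:-1])
        np.testing.assert_array_equal(x[0, 12:], 0)

    def test_covariate_series_regresses_to_zero(self, rng):
        cov = rng.standard_normal(40)
        data = np.broadcast_to(cov, (2, 2, 2, 40)).copy()
        img = toy_image(data)
        nuis = m3.NuisanceSet(wm_signal=cov)
        resid = m3.regress_nuisance(img, nuis)
        np.testing.assert_allclose(resid.data, 0, atol=1e-10)

    def test_residuals_match_normal_equations_oracle(self, rng):
        data = rng.standard_normal((5, 2, 2, 30))
        img = toy_image(data)
        motion = rng.standard_normal((30, 6))
        wm = rng.standard_normal(30)
        nuis = m3.make_nuisance_set(motion6=motion, wm_signal=wm,
                                    n_timepoints=30)
        resid = m3.regress_nuisance(img, nuis)
        design = np.hstack([
            np.ones((30, 1)), friston24(motion), wm.reshape(-1, 1),
            np.linspace(-1, 1, 30).reshape(-1, 1),
        ])
        hat = design @ np.linalg.pinv(design)
        for v in [(0, 0, 0), (3, 1, 1), (4, 0, 1)]:
            y = data[v]
            np.testing.assert_allclose(resid.data[v], y - hat @ y, atol=1e-8)
        # residuals orthogonal to every covariate column
        flat = resid.data[img.mask]
        np.testing.assert_allclose(flat @ design, 0, atol=1e-7)

    def test_gsr_removes_shared_component_and_is_idempotent(self, rng):
        shared = np.sin(np.linspace(0, 8, 50))
        data = rng.standard_normal((4, 4, 2, 50)) + shared
        img = toy_image(data)
        nuis = m3.make_nuisance_set(img=img)
        once = m3.regress_nuisance(img, nuis, include_gsr=True)
        mean_series = once.data[once.mask].mean(axis=0)
        np.testing.assert_allclose(mean_series, 0, atol=1e-10)
        nuis2 = m3.make_nuisance_set(img=once)
        twice = m3.regress_nuisance(once, nuis2, include_gsr=True)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-8)

    def test_length_mismatch_rejected(self, rng):
        img = toy_image(rng.standard_normal((2, 2, 2, 30)))
        with pytest.raises(ValueError, match="match"):
            m3.regress_nuisance(img, m3.NuisanceSet(wm_signal=np.zeros(29)))


class TestBandpass:
    def test_in_band_sinusoid_passes_unchanged(self):
        img = sinusoid_image(0.05)
        out = m3.bandpass(img, 0.01, 0.10)
        np.testing.assert_allclose(out.data, img.data, atol=1e-10)

    def test_out_of_band_sinusoid_rejected(self):
        img = sinusoid_image(0.2)
        out = m3.bandpass(img, 0.01, 0.10)
        np.testing.assert_allclose(out.data, 0, atol=1e-10)

    def test_spectrum_equals_masked_input_spectrum(self, rng):
        data = rng.standard_normal((2, 2, 1, 64))
        img = toy_image(data)
        out = m3.bandpass(img, 0.02, 0.08)
        freqs = np.fft.rfftfreq(64, d=2.0)
        keep = (freqs >= 0.02) & (freqs <= 0.08)
        spec_in = np.fft.rfft(data, axis=-1)
        spec_out = np.fft.rfft(out.data, axis=-1)
        np.testing.assert_allclose(spec_out[..., keep], spec_in[..., keep],
                                   atol=1e-8)
        np.testing.assert_allclose(spec_out[..., ~keep], 0, atol=1e-8)

    def test_band_outside_nyquist_rejected(self):
        img = sinusoid_image(0.05)
        with pytest.raises(ValueError, match="Nyquist"):
            m3.bandpass(img, 0.01, 0.5)


class TestAlff:
    def test_linear_in_amplitude(self):
        a1 = m3.compute_alff(sinusoid_image(0.05, amp=1.0))
        a2 = m3.compute_alff(sinusoid_image(0.05, amp=2.0))
        ratio = a2.values[0, 0, 0] / a1.values[0, 0, 0]
        assert ratio == pytest.approx(2.0, rel=1e-9)

    def test_constant_series_gives_zero(self):
        img = toy_image(np.full((2, 2, 1, 50), 3.7))
        np.testing.assert_allclose(m3.compute_alff(img).values, 0, atol=1e-12)

    def test_white_noise_alff_scales_with_sd(self, rng):
        base = rng.standard_normal((6, 6, 4, 200))
        small = m3.compute_alff(toy_image(base))
        large = m3.compute_alff(toy_image(3.0 * base))
        ratio = large.values.mean() / small.values.mean()
        assert ratio == pytest.approx(3.0, rel=1e-9)
        assert small.values.mean() > 0


class TestReho:
    def test_identical_neighbors_give_w_one(self, rng):
        series = rng.standard_normal(30)
        data = np.broadcast_to(series, (5, 5, 5, 30)).copy()
        w = m3.compute_reho(toy_image(data))
        assert w.values[2, 2, 2] == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_k3_concordance(self):
        """Three voxel series with hand-computable rank sums (1D column)."""
        s1 = [1.0, 2.0, 3.0, 4.0]
        s2 = [2.0, 1.0, 4.0, 3.0]
        s3 = [1.5, 2.5, 3.5, 4.5]
        data = np.zeros((1, 1, 3, 4))
        data[0, 0, 0] = s1
        data[0, 0, 1] = s2
        data[0, 0, 2] = s3
        # center voxel's 27-neighborhood holds exactly these K=3 series;
        # ranks: s1 -> 1234, s2 -> 2143, s3 -> 1234; rank sums (4,5,10,11),
        # mean 7.5, S = 12.25+6.25+6.25+12.25 = 37, W = 12*37/(9*(64-4))
        w = m3.compute_reho(toy_image(data))
        assert w.values[0, 0, 1] == pytest.approx(12 * 37 / (9 * 60), abs=1e-12)

    def test_values_bounded_and_null_declines_with_k(self, rng):
        data = rng.standard_normal((8, 8, 6, 120))
        w27 = m3.compute_reho(toy_image(data), neighborhood=27)
        w7 = m3.compute_reho(toy_image(data), neighborhood=7)
        assert np.all((w27.values >= 0) & (w27.values <= 1))
        # under independence W concentrates near 1/K: smaller for larger K
        assert w27.values[2:-2, 2:-2, 2:-2].mean() < w7.values[2:-2, 2:-2, 2:-2].mean()

    def test_invalid_neighborhood_rejected(self, rng):
        with pytest.raises(ValueError, match="neighborhood"):
            m3.compute_reho(toy_image(rng.standard_normal((3, 3, 3, 20))), 9)


class TestDegreeCentrality:
    def test_identical_series_count_all_others(self, rng):
        series = rng.standard_normal(30)
        data = np.broadcast_to(series, (3, 1, 1, 30)).copy()
        dc = m3.compute_dc(toy_image(data))
        np.testing.assert_array_equal(dc.values.ravel(), [2, 2, 2])

    def test_threshold_is_strictly_positive_sided(self, rng):
        series = rng.standard_normal(30)
        data = np.stack([series, -series])[:, None, None, :]
        dc = m3.compute_dc(toy_image(data))
        np.testing.assert_array_equal(dc.values.ravel(), [0, 0])

    def test_matches_brute_force_correlation_count(self, rng):
        data = rng.standard_normal((10, 1, 1, 40))
        img = toy_image(data)
        dc = m3.compute_dc(img, r_threshold=0.25)
        flat = data.reshape(10, 40)
        expected = np.zeros(10)
        for i in range(10):
            for j in range(10):
                if i != j and sps.pearsonr(flat[i], flat[j])[0] > 0.25:
                    expected[i] += 1
        np.testing.assert_array_equal(dc.values.ravel(), expected)

    def test_weighted_variant_sums_correlations(self, rng):
        data = rng.standard_normal((6, 1, 1, 40))
        img = toy_image(data)
        dcw = m3.compute_dc(img, r_threshold=0.25, weighted=True)
        flat = data.reshape(6, 40)
        corr = np.corrcoef(flat)
        np.fill_diagonal(corr, 0.0)
        expected = (corr * (corr > 0.25)).sum(axis=1)
        np.testing.assert_allclose(dcw.values.ravel(), expected, atol=1e-10)


class TestVmhc:
    def test_mirror_symmetric_image_gives_one(self, symmetric_image):
        img, _, _ = symmetric_image
        v = m3.compute_vmhc(img)
        np.testing.assert_allclose(v.values[img.mask], 1.0, atol=1e-9)

    def test_sign_flipped_mirror_gives_minus_one(self, rng):
        half = rng.standard_normal((2, 3, 3, 30))
        data = np.concatenate([half, -half[::-1]], axis=0)
        v = m3.compute_vmhc(toy_image(data))
        np.testing.assert_allclose(v.values, -1.0, atol=1e-9)

    def test_matches_pairwise_correlation_oracle_and_symmetry(self, rng):
        data = rng.standard_normal((4, 3, 3, 50))
        img = toy_image(data)
        v = m3.compute_vmhc(img)
        for x in range(4):
            for y in range(3):
                for z in range(3):
                    r = sps.pearsonr(data[x, y, z], data[3 - x, y, z])[0]
                    assert v.values[x, y, z] == pytest.approx(r, abs=1e-10)
        np.testing.assert_allclose(v.values, v.values[::-1], atol=1e-12)

    def test_odd_x_extent_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            m3.compute_vmhc(toy_image(rng.standard_normal((3, 2, 2, 20))))


class TestStandardizeAndSmooth:
    def test_fisher_z_closed_form(self):
        vals = np.array([[[0.0, 0.5], [-0.5, 0.9]]])
        z = m3.standardize_map(m3.MetricMap(vals, "VMHC"), "fisher_z")
        assert z.values[0, 0, 0] == 0.0
        assert z.values[0, 0, 1] == pytest.approx(0.5493, abs=1e-4)
        assert z.values[0, 1, 0] == pytest.approx(-0.5493, abs=1e-4)

    def test_fisher_z_clamps_at_unit_but_rejects_beyond(self):
        ok = m3.standardize_map(m3.MetricMap(np.full((1, 1, 1), 1.0), "VMHC"),
                                "fisher_z")
        assert np.isfinite(ok.values).all()
        with pytest.raises(ValueError, match="fisher_z"):
            m3.standardize_map(m3.MetricMap(np.full((1, 1, 1), 1.5), "VMHC"),
                               "fisher_z")

    def test_mean_sd_z_normalizes_in_mask(self, rng):
        vals = rng.standard_normal((4, 4, 4)) * 5 + 2
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:, 1:, 1:] = True
        z = m3.standardize_map(m3.MetricMap(vals, "ALFF"), "mean_sd_z", mask)
        assert z.values[mask].mean() == pytest.approx(0, abs=1e-12)
        assert z.values[mask].std() == pytest.approx(1, abs=1e-12)

    def test_smoothing_identity_constant_and_kernel_mass(self):
        m = m3.MetricMap(np.random.default_rng(0).standard_normal((8, 8, 8)),
                         "ALFF")
        same = m3.smooth_gaussian(m, 0.0)
        np.testing.assert_array_equal(same.values, m.values)

        const = m3.MetricMap(np.full((9, 9, 9), 2.5), "ALFF")
        sm = m3.smooth_gaussian(const, 6.0, (3, 3, 3))
        np.testing.assert_allclose(sm.values, 2.5, atol=1e-9)

        delta = np.zeros((15, 15, 15))
        delta[7, 7, 7] = 1.0
        blurred = m3.smooth_gaussian(m3.MetricMap(delta, "ALFF"), 4.0, (3, 3, 3))
        assert blurred.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            m3.smooth_gaussian(m3.MetricMap(np.zeros((2, 2, 2)), "ALFF"), -1.0)
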