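"""Band areas, lateral grouping, surface detection, cropping, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf

from ramanpen import (
    Band,
    DepthProfile,
    SurfaceDetectionError,
    SyntheticConfig,
    ValidationError,
    aggregate_profiles,
    band_auc,
    crop_to_surface,
    detect_surface,
    extract_profile,
    normalize_profile,
    scan_to_profiles,
    simulate_skin_scan,
    split_lateral_groups,
)
from ramanpen.preprocess import preprocess_scan


class TestBandAUC:
    def test_constant_spectrum_integrates_to_zero(self, bands):
        wn = np.arange(501.0, 1636.0)
        assert band_auc(wn, np.full(wn.size, 42.0), bands["caffeine"]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_triangle_closed_form(self):
        # triangle peak of height 8 and base 10 cm⁻¹, vertices on samples
        wn = np.arange(501.0, 700.0)
        y = np.interp(wn, [550.0, 555.0, 560.0], [0.0, 8.0, 0.0])
        band = Band("tri", 555.0, 540.0, 570.0)
        assert band_auc(wn, y, band) == pytest.approx(8.0 * 10.0 / 2.0, rel=1e-12)

    def test_gaussian_closed_form_against_fine_grid(self):
        a, s = 7.0, 4.0
        wn = np.arange(501.0, 700.0)  # 1 cm⁻¹ sampling
        y = a * np.exp(-0.5 * ((wn - 600.0) / s) ** 2)
        band = Band("g", 600.0, 560.0, 640.0)
        got = band_auc(wn, y, band)
        fine = np.linspace(560.0, 640.0, 8001)
        oracle = np.trapezoid(a * np.exp(-0.5 * ((fine - 600.0) / s) ** 2), fine)
        assert got == pytest.approx(oracle, rel=5e-3)
        assert got == pytest.approx(a * s * np.sqrt(2 * np.pi), rel=5e-3)

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(0.1, 100.0))
    def test_linearity_in_amplitude(self, scale):
        wn = np.arange(501.0, 700.0)
        y = np.exp(-0.5 * ((wn - 600.0) / 4.0) ** 2)
        band = Band("g", 600.0, 560.0, 640.0)
        assert band_auc(wn, scale * y, band) == pytest.approx(
            scale * band_auc(wn, y, band), rel=1e-9
        )


class TestLateralGrouping:
    def test_ten_positions_three_groups(self, bands):
        cfg = SyntheticConfig(seed=0, n_lateral=10, n_depth=10, wn_step=4.0)
        scan, _ = simulate_skin_scan(cfg)
        groups = split_lateral_groups(scan, 3)
        sizes = [g.metadata["lateral_group"] for g in groups]
        assert sizes == ["0:3", "3:6", "6:10"]
        assert all(g.n_lateral == 1 for g in groups)

    def test_single_group_is_full_mean(self, small_cfg):
        scan, _ = simulate_skin_scan(small_cfg)
        (g,) = split_lateral_groups(scan, 1)
        np.testing.assert_allclose(
            g.intensities[0], scan.intensities.mean(axis=0), rtol=1e-12
        )

    def test_identity_partition(self, small_cfg):
        scan, _ = simulate_skin_scan(small_cfg)
        groups = split_lateral_groups(scan, scan.n_lateral)
        for i, g in enumerate(groups):
            np.testing.assert_array_equal(g.intensities[0], scan.intensities[i])

    def test_too_many_groups_rejected(self, small_cfg):
        scan, _ = simulate_skin_scan(small_cfg)
        with pytest.raises(ValidationError):
            split_lateral_groups(scan, scan.n_lateral + 1)


class TestExtractProfile:
    def test_zero_scan_gives_zero_profile(self, flat_scan, bands):
        zero = flat_scan.with_intensities(np.zeros_like(flat_scan.intensities))
        (g,) = split_lateral_groups(zero, 1)
        prof = extract_profile(g, bands["caffeine"])
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)
        assert prof.state == "raw"

    def test_depth_constant_band_gives_constant_profile(self, bands):
        cfg = SyntheticConfig(
            seed=0,
            n_lateral=4,
            n_depth=20,
            wn_step=2.0,
            noise_sd=0.0,
            spike_rate=0.0,
            surface_z_um=0.0,
            attenuation_len_um=1e9,
            diffusion_coeff_um2_h=1e9,
            psf_fwhm_um=0.05,
        )
        scan, _ = simulate_skin_scan(cfg)
        (g,) = split_lateral_groups(scan, 1)
        prof = extract_profile(g, bands["caffeine"])
        interior = prof.values[2:]  # below the (blurred) surface at z=0
        assert np.ptp(interior) < 0.02 * np.abs(interior).max()

    def test_erfc_amplitude_profile_monotone(self, bands):
        from ramanpen import PreprocessConfig, subtract_background

        cfg = SyntheticConfig(
            seed=0,
            n_lateral=4,
            n_depth=40,
            wn_step=2.0,
            noise_sd=0.0,
            spike_rate=0.0,
        )
        scan, _ = simulate_skin_scan(cfg)
        clean = subtract_background(scan, PreprocessConfig(shape_size=200))
        (g,) = split_lateral_groups(clean, 1)
        prof = extract_profile(g, bands["caffeine"])
        # beyond the PSF shoulder the erfc law is monotone non-increasing
        # (up to the residual of the fluorescence floor, ≪ the band signal)
        shoulder = cfg.surface_z_um + 2 * cfg.psf_fwhm_um
        below = prof.values[prof.depths >= shoulder]
        assert np.all(np.diff(below) <= 5e-4 * np.abs(below[0]))


class TestSurfaceDetection:
    def test_ideal_step(self):
        depths = np.arange(0.0, 25.0, 0.5)
        values = np.where(depths >= 5.0, 80.0, 0.0)
        prof = DepthProfile(depths, values, band="keratin")
        assert detect_surface(prof) == pytest.approx(5.0, abs=0.25)

    def test_erf_edge_centered_at_z0(self):
        z0, fwhm = 6.0, 1.86
        sigma = fwhm / 2.3548
        depths = np.arange(0.0, 25.0, 0.5)
        values = 50.0 * 0.5 * (1 + erf((depths - z0) / (np.sqrt(2) * sigma)))
        prof = DepthProfile(depths, values, band="keratin")
        assert detect_surface(prof) == pytest.approx(z0, abs=0.25)

    def test_monotone_decreasing_profile_rejected(self):
        depths = np.arange(0.0, 10.0, 0.5)
        prof = DepthProfile(depths, 100.0 - 5.0 * depths, band="keratin")
        with pytest.raises(SurfaceDetectionError):
            detect_surface(prof)

    def test_recovers_simulated_surface(self, bands):
        for seed in (1, 2, 3):
            cfg = SyntheticConfig(seed=seed, n_lateral=6, wn_step=2.0, noise_sd=0.15)
            scan, truth = simulate_skin_scan(cfg)
            clean = preprocess_scan(
                scan, __import__("ramanpen").PreprocessConfig(shape_size=200)
            )
            (g,) = split_lateral_groups(clean, 1)
            ker = extract_profile(g, bands["keratin"])
            assert detect_surface(ker) == pytest.approx(truth.surface_z, abs=0.25)


class TestCropping:
    @staticmethod
    def _profile():
        depths = np.arange(0.0, 25.5, 0.5)
        return DepthProfile(depths, 100.0 + depths, band="caffeine")

    def test_crop_at_first_depth_only_rezeros(self):
        prof = self._profile()
        out = crop_to_surface(prof, prof.depths[0])
        np.testing.assert_allclose(out.depths, prof.depths - prof.depths[0])
        np.testing.assert_allclose(out.values, prof.values)
        assert out.state == "cropped"

    def test_crop_at_2um_on_25um_grid(self):
        out = crop_to_surface(self._profile(), 2.0)
        assert out.depths[0] == 0.0
        assert out.depths[-1] == pytest.approx(23.0)

    def test_inserted_point_is_linear_interpolation(self):
        prof = self._profile()
        out = crop_to_surface(prof, 2.3)
        assert out.depths[0] == 0.0
        assert out.values[0] == pytest.approx(np.interp(2.3, prof.depths, prof.values))

    def test_crop_idempotent_at_zero(self):
        once = crop_to_surface(self._profile(), 2.0)
        twice = crop_to_surface(once, 0.0)
        np.testing.assert_allclose(twice.depths, once.depths)
        np.testing.assert_allclose(twice.values, once.values)

    def test_surface_beyond_range_rejected(self):
        with pytest.raises(ValidationError):
            crop_to_surface(self._profile(), 30.0)


class TestNormalization:
    @staticmethod
    def _cropped(values):
        depths = np.arange(0.0, float(len(values)) / 2, 0.5)
        return DepthProfile(depths, np.asarray(values, float), band="x", state="cropped")

    def test_constant_keratin_divides_exactly(self):
        drug = self._cropped([1.0, 2.0, 3.0, 4.0])
        ker = DepthProfile(drug.depths, np.full(4, 5.0), band="keratin", state="cropped")
        out = normalize_profile(drug, ker)
        np.testing.assert_allclose(out.values, drug.values / 5.0, rtol=1e-12)
        assert out.state == "normalized"

    @settings(derandomize=True, max_examples=25)
    @given(c=st.floats(1e-3, 1e6))
    def test_scale_invariance(self, c):
        drug = self._cropped([1.0, 2.0, 3.0, 4.0])
        ker = self._cropped([5.0, 4.0, 3.0, 2.0])
        base = normalize_profile(drug, ker)
        scaled = normalize_profile(
            self._cropped(c * drug.values), self._cropped(c * ker.values)
        )
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9)

    def test_nonpositive_keratin_mean_rejected(self):
        drug = self._cropped([1.0, 2.0])
        ker = self._cropped([-1.0, 0.5])
        with pytest.raises(ValidationError, match="keratin mean"):
            normalize_profile(drug, ker)

    def test_grid_mismatch_rejected(self):
        drug = self._cropped([1.0, 2.0, 3.0])
        ker = self._cropped([1.0, 2.0])
        with pytest.raises(ValidationError, match="grid"):
            normalize_profile(drug, ker)

    def test_doubled_caffeine_amplitude_doubles_profile(self, bands, small_pre_cfg):
        profs = {}
        for fac in (1.0, 2.0):
            cfg = SyntheticConfig(
                seed=9, n_lateral=6, wn_step=2.0, noise_sd=0.05,
                enhancer_factor=fac, spike_rate=0.0,
            )
            scan, _ = simulate_skin_scan(cfg)
            clean = preprocess_scan(scan, small_pre_cfg)
            reps = scan_to_profiles(clean, bands["caffeine"], bands["keratin"], 3)
            profs[fac] = aggregate_profiles(reps).mean
        lo = min(profs[1.0].depths[-1], profs[2.0].depths[-1])
        grid = np.linspace(0, lo, 30)
        v1 = np.interp(grid, profs[1.0].depths, profs[1.0].values)
        v2 = np.interp(grid, profs[2.0].depths, profs[2.0].values)
        ratio = np.trapezoid(v2, grid) / np.trapezoid(v1, grid)
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestAggregation:
    @staticmethod
    def _norm(values, step=0.5):
        depths = step * np.arange(len(values))
        return DepthProfile(depths, np.asarray(values, float), band="caffeine",
                            state="normalized")

    def test_identical_replicates(self):
        reps = [self._norm([1.0, 2.0, 3.0]) for _ in range(4)]
        pset = aggregate_profiles(reps)
        np.testing.assert_allclose(pset.mean.values, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(pset.mean.sd, 0.0, atol=1e-12)

    def test_two_constant_profiles_closed_form(self):
        a, b = 3.0, 7.0
        pset = aggregate_profiles([self._norm([a] * 5), self._norm([b] * 5)])
        np.testing.assert_allclose(pset.mean.values, (a + b) / 2)
        np.testing.assert_allclose(pset.mean.sd, abs(a - b) / np.sqrt(2), rtol=1e-12)

    def test_sd_estimates_known_noise(self):
        rng = np.random.default_rng(12)
        sigma, n = 0.3, 9
        reps = [self._norm(5.0 + rng.normal(0, sigma, 40)) for _ in range(n)]
        pset = aggregate_profiles(reps)
        med_sd = np.median(pset.mean.sd)
        assert abs(med_sd - sigma) < 0.5 * sigma  # χ² bounds, n=9

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_profiles([self._norm([1.0, 2.0])])

    def test_mixed_states_rejected(self):
        a = self._norm([1.0, 2.0])
        b = DepthProfile(a.depths, a.values, band="caffeine", state="raw")
        with pytest.raises(ValidationError, match="share"):
            aggregate_profiles([a, b])


def test_pipeline_scale_invariance(bands, small_cfg, small_pre_cfg):
    """Cropped, normalized profiles are invariant to global intensity rescaling."""
    scan, _ = simulate_skin_scan(small_cfg)
    scaled = scan.with_intensities(scan.intensities * 7.5)
    base = scan_to_profiles(
        preprocess_scan(scan, small_pre_cfg), bands["caffeine"], bands["keratin"]
    )
    resc = scan_to_profiles(
        preprocess_scan(scaled, small_pre_cfg), bands["caffeine"], bands["keratin"]
    )
    for p, q in zip(base, resc):
        np.testing.assert_allclose(q.depths, p.depths, rtol=1e-9)
        np.testing.assert_allclose(q.values, p.values, rtol=1e-9, atol=1e-9)


def test_recovered_profile_correlates_with_truth(bands, small_pre_cfg):
    """Noise-free pipeline output tracks the PSF-blurred erfc ground truth."""
    cfg = SyntheticConfig(
        seed=0, n_lateral=6, wn_step=2.0, noise_sd=0.0, spike_rate=0.0
    )
    scan, truth = simulate_skin_scan(cfg)
    clean = preprocess_scan(scan, small_pre_cfg)
    (prof,) = scan_to_profiles(clean, bands["caffeine"], bands["keratin"], 1)
    # model: the true erfc concentration law blurred by the axial PSF,
    # expressed in skin-depth coordinates
    from ramanpen.synthetic import _psf_convolve

    stage = prof.depths + truth.surface_z
    model = _psf_convolve(
        lambda z: truth.concentration(z - truth.surface_z), stage, cfg.psf_fwhm_um
    )
    r = np.corrcoef(prof.values, model)[0, 1]
    assert r > 0.98
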