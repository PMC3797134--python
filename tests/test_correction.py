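import numpy as np
import pytest

from aptcest import (FitConfig, PhantomSpec, SaturationParams, ZSpectrum,
                     b0_map, center_zspectrum, correct_stack,
                     correct_zspectrum, estimate_b0, fit_zspectrum,
                     generate_phantom_stack, simulate_zspectrum, water_pool)
from aptcest.phantom import TISSUE_CODES


def _asym35(zs: ZSpectrum) -> float:
    return zs.value_at(-3.5) - zs.value_at(3.5)


class TestFit:
    def test_noise_free_fit_is_exact_at_measured_offsets(
            self, sat, scanner, schedule, tumor_pools):
        zs = simulate_zspectrum(tumor_pools, sat, scanner, schedule)
        fit = fit_zspectrum(zs)
        resid = fit(zs.offsets) - zs.values
        z_range = np.ptp(zs.values)
        assert np.sqrt(np.mean(resid**2)) < 1e-3 * z_range

    def test_symmetric_spectrum_centre_is_zero(self, sat, scanner, schedule,
                                               water_only):
        zs = simulate_zspectrum(water_only, sat, scanner, schedule)
        fit = fit_zspectrum(zs)
        assert abs(fit.gaussian.center) < 0.01

    def test_flat_spectrum_fits_trivially(self, scanner, schedule, two_pool):
        zs = simulate_zspectrum(two_pool, SaturationParams(b1_amplitude=0.0),
                                scanner, schedule)
        fit = fit_zspectrum(zs)
        assert fit.gaussian.amplitude < 1e-3
        assert np.allclose(fit(np.linspace(-5.5, 5.5, 23)), 1.0, atol=1e-6)

    def test_too_few_points_per_side_rejected(self):
        offsets = np.arange(-1.5, 1.51, 0.5)
        with pytest.raises(ValueError):
            fit_zspectrum(ZSpectrum(offsets, np.ones_like(offsets)))


class TestB0Estimate:
    @pytest.mark.parametrize("injected, tol", [
        (0.0, 0.01), (0.3, 0.02), (-0.5, 0.05), (0.47, 0.02), (-0.23, 0.02),
    ])
    def test_injected_shift_recovered(self, injected, tol, sat, scanner,
                                      schedule, tumor_pools):
        zs = simulate_zspectrum(tumor_pools, sat, scanner, schedule,
                                b0_offset=injected)
        est = estimate_b0(fit_zspectrum(zs))
        assert est.reliable
        assert est.b0 == pytest.approx(injected, abs=tol)

    def test_flat_spectrum_flagged_unreliable(self, scanner, schedule,
                                              two_pool):
        zs = simulate_zspectrum(two_pool, SaturationParams(b1_amplitude=0.0),
                                scanner, schedule)
        est = estimate_b0(fit_zspectrum(zs))
        assert not est.reliable


class TestCentering:
    def test_zero_shift_correction_is_identity_at_nodes(
            self, sat, scanner, schedule, tumor_pools):
        zs = simulate_zspectrum(tumor_pools, sat, scanner, schedule)
        fit = fit_zspectrum(zs)
        corr = center_zspectrum(zs, fit, 0.0)
        assert np.allclose(corr.values, fit(zs.offsets), atol=1e-12)
        assert corr.state == "b0-corrected"
        assert not corr.extrapolated.any()

    def test_large_shift_refused(self, sat, scanner, schedule, tumor_pools):
        zs = simulate_zspectrum(tumor_pools, sat, scanner, schedule)
        fit = fit_zspectrum(zs)
        with pytest.raises(ValueError):
            center_zspectrum(zs, fit, 1.2)

    def test_out_of_range_offsets_flagged_extrapolated(
            self, sat, scanner, schedule, tumor_pools):
        zs = simulate_zspectrum(tumor_pools, sat, scanner, schedule,
                                b0_offset=0.3)
        fit = fit_zspectrum(zs)
        corr = center_zspectrum(zs, fit, 0.3)
        assert corr.extrapolated[corr.offsets == 6.0][0]
        assert not corr.extrapolated[np.abs(corr.offsets) < 5.5].any()

    @pytest.mark.parametrize("pools_name", ["tumor_pools", "cord_pools"])
    def test_shift_then_correct_roundtrip_preserves_asymmetry(
            self, pools_name, sat, scanner, schedule, request):
        """Injected B0 shifts in [-0.5, 0.5] ppm change the corrected
        APT-weighted value by < 0.1 percentage points (noise-free)."""
        pools = request.getfixturevalue(pools_name)
        base = _asym35(correct_zspectrum(
            simulate_zspectrum(pools, sat, scanner, schedule)))
        for injected in (-0.5, -0.31, -0.13, 0.055, 0.2, 0.47, 0.5):
            zs = simulate_zspectrum(pools, sat, scanner, schedule,
                                    b0_offset=injected)
            corr = correct_zspectrum(zs)
            assert abs(_asym35(corr) - base) < 1e-3  # 0.1 pp

    def test_correction_is_idempotent(self, sat, scanner, schedule,
                                      tumor_pools):
        corr = correct_zspectrum(simulate_zspectrum(
            tumor_pools, sat, scanner, schedule, b0_offset=0.3))
        refit = fit_zspectrum(corr)
        est2 = estimate_b0(refit)
        assert abs(est2.b0) <= 0.02
        corr2 = center_zspectrum(corr, refit, est2.b0)
        assert abs(_asym35(corr2) - _asym35(corr)) < 5e-4  # 0.05 pp


class TestB0Map:
    def test_zero_field_phantom_maps_to_zero(self, sat, scanner, schedule):
        spec = PhantomSpec(image_size=32, noise_sigma=0.0, b0_amplitude=0.0)
        stack, _ = generate_phantom_stack(spec, schedule, sat, scanner)
        bmap = b0_map(stack)
        vals = bmap.values[np.isfinite(bmap.values)]
        assert np.max(np.abs(vals)) <= 0.02

    def test_linear_ramp_field_recovered(self, sat, scanner, schedule):
        size = 32
        ramp = np.tile(np.linspace(-0.4, 0.4, size), (size, 1))
        spec = PhantomSpec(image_size=size, noise_sigma=0.0, b0_field=ramp,
                           b0_quantization=0.0)
        stack, truth = generate_phantom_stack(spec, schedule, sat, scanner)
        bmap = b0_map(stack)
        sel = np.isfinite(bmap.values)
        slope_true = np.polyfit(np.nonzero(sel)[1], truth.b0_field[sel], 1)[0]
        slope_est = np.polyfit(np.nonzero(sel)[1], bmap.values[sel], 1)[0]
        assert slope_est == pytest.approx(slope_true, rel=0.05)

    def test_smooth_field_rms_error_within_budget(self, phantom_nf):
        """Whole-phantom pixel-wise B0 recovery: RMS error <= 0.03 ppm."""
        _, stack, truth = phantom_nf
        bmap = b0_map(stack)
        sel = np.isfinite(bmap.values)
        err = bmap.values[sel] - truth.b0_field[sel]
        assert np.sqrt(np.mean(err**2)) <= 0.03

    def test_map_is_deterministic(self, phantom_noisy):
        _, stack, _ = phantom_noisy
        a = b0_map(stack)
        b = b0_map(stack)
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_estimate_error_degrades_monotonically_with_noise(
            self, sat, scanner, schedule):
        """Seeded sweep: B0 RMS error is non-decreasing in noise sigma."""
        rms = []
        for sigma in (0.0, 0.01, 0.03, 0.08):
            spec = PhantomSpec(image_size=24, noise_sigma=sigma, seed=5)
            stack, truth = generate_phantom_stack(spec, schedule, sat, scanner)
            bmap = b0_map(stack)
            sel = np.isfinite(bmap.values)
            err = bmap.values[sel] - truth.b0_field[sel]
            rms.append(np.sqrt(np.mean(err**2)))
        assert np.all(np.diff(rms) >= -1e-6)

    def test_stack_path_agrees_with_per_spectrum_path(self, phantom_nf):
        """Vectorized Guo-based correction matches the nonlinear
        single-spectrum fit closely on noise-free pixels."""
        _, stack, truth = phantom_nf
        from aptcest import assemble_zspectra
        spectra = assemble_zspectra(stack)
        corrected, bmap = correct_stack(spectra)
        for r, c in [(8, 32), (52, 32), (32, 5)]:
            if not spectra.mask[r, c]:
                continue
            est = estimate_b0(fit_zspectrum(spectra.spectrum_at(r, c)))
            assert bmap.values[r, c] == pytest.approx(est.b0, abs=0.01)
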