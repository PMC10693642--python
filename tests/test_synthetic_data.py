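"""Generator correctness: closed-form statistics and determinism."""

import numpy as np
import pytest

from cytorheo import (ImageGrid, MediumModel, SyntheticSpec, WLCSpec,
                      bundle_parameter, compute_msd, contour_length,
                      ensemble_msd, extract_line_profile, render_aster_image,
                      render_bundle_image, sample_lengths, simulate_bead,
                      simulate_bead_pairs, simulate_wlc_2d, thermal_energy)


def _spec(medium, n_particles=40, n_frames=2000, seed=0, **kw):
    return SyntheticSpec(n_particles=n_particles, n_frames=n_frames,
                         dt=1 / 138, medium=medium, bead_diameter=2.0,
                         temperature=294.0, seed=seed, **kw)


class TestBeadSimulation:
    def test_viscous_msd_matches_stokes_einstein(self):
        """Free diffusion: ensemble MSD = 4 D tau with D = kT/(6 pi eta a)."""
        eta = 0.002
        ens = simulate_bead(_spec(MediumModel("viscous", eta=eta), seed=11))
        msd = ensemble_msd([compute_msd(tr) for tr in ens], aggregate="mean")
        d = thermal_energy(294.0) / (6 * np.pi * eta * 1.0)
        short = msd.tau < 0.5      # well-averaged lags
        ratio = msd.msd[short] / (4 * d * msd.tau[short])
        # 3 standard errors: relative SE of a time-averaged MSD over the
        # ensemble is roughly sqrt(2 k / (N n)) at lag k
        assert np.all(np.abs(ratio - 1)
                      < 3 * np.sqrt(2 * msd.tau[short] * 138 / (40 * 2000)) + 0.05)

    def test_kelvin_voigt_equipartition(self):
        """Caged bead positional variance -> kT / (6 pi a G0)."""
        g0 = 0.039
        ens = simulate_bead(_spec(
            MediumModel("kelvin_voigt", G0=g0, eta=0.005),
            n_particles=100, n_frames=10_000, seed=7))
        var = np.mean([np.var(tr.x) + np.var(tr.y) for tr in ens]) / 2
        expected = thermal_energy(294.0) / (6 * np.pi * 1.0 * g0)
        assert var == pytest.approx(expected, rel=0.05)

    def test_kelvin_voigt_zero_stiffness_is_diffusive(self):
        """G0 = 0 reduces to pure diffusion with the same viscosity."""
        ens = simulate_bead(_spec(
            MediumModel("kelvin_voigt", G0=0.0, eta=0.002), seed=3))
        msd = ensemble_msd([compute_msd(tr) for tr in ens], aggregate="mean")
        slope = np.polyfit(np.log(msd.tau), np.log(msd.msd), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_power_law_alpha_one_has_uncorrelated_increments(self):
        """alpha = 1 is Brownian: off-diagonal increment covariance -> 0."""
        ens = simulate_bead(_spec(
            MediumModel("power_law", A=0.01, alpha=1.0),
            n_particles=60, n_frames=3000, seed=5))
        steps = np.concatenate([np.diff(tr.x) for tr in ens])
        c = np.corrcoef(steps[:-1], steps[1:])[0, 1]
        assert abs(c) < 3 / np.sqrt(len(steps))

    def test_power_law_msd_amplitude_and_exponent(self):
        med = MediumModel("power_law", A=0.05, alpha=0.5)
        ens = simulate_bead(_spec(med, n_particles=50, n_frames=4000, seed=9))
        msd = ensemble_msd([compute_msd(tr) for tr in ens], aggregate="mean")
        closed = med.msd_2d(msd.tau, 1.0, 294.0)
        sel = msd.tau < 1.0
        assert np.median(msd.msd[sel] / closed[sel]) == pytest.approx(1.0, rel=0.05)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MediumModel("viscous", eta=0.0)
        with pytest.raises(ValueError):
            MediumModel("power_law", A=0.1, alpha=1.5)
        with pytest.raises(ValueError):
            _spec(MediumModel("viscous", eta=1e-3), n_frames=1)


class TestBeadPairs:
    def test_zero_coupling_is_independent(self):
        spec = _spec(MediumModel("kelvin_voigt", G0=0.5, eta=0.01),
                     n_particles=0, n_frames=1500, seed=2)
        ens = simulate_bead_pairs(spec, [5.0, 8.0], coupling_amplitude=0.0)
        a, b = ens.trajectories[0], ens.trajectories[1]
        da, db = np.diff(a.x), np.diff(b.x)
        assert abs(np.corrcoef(da, db)[0, 1]) < 3 / np.sqrt(len(da))

    def test_recorded_truth_is_one_over_r(self):
        spec = _spec(MediumModel("viscous", eta=0.01), n_particles=0,
                     n_frames=100, seed=2)
        ens = simulate_bead_pairs(spec, [4.0], coupling_amplitude=0.02)
        d_rr = ens.truth["D_rr"]
        assert d_rr(4.0, 1.0) == pytest.approx(0.02 / 4.0)
        assert d_rr(8.0, 1.0) == pytest.approx(0.02 / 8.0)

    def test_common_displacement_covariance(self):
        """Cross-covariance of along-axis displacements equals A*tau/r."""
        spec = _spec(MediumModel("kelvin_voigt", G0=2.0, eta=0.02),
                     n_particles=0, n_frames=20_000, seed=6)
        r, amp = 5.0, 0.05
        ens = simulate_bead_pairs(spec, [r], coupling_amplitude=amp)
        a, b = ens.trajectories
        k = 14
        da = a.x[k:] - a.x[:-k]
        db = b.x[k:] - b.x[:-k]
        tau = k * spec.dt
        assert np.mean(da * db) == pytest.approx(amp * tau / r, rel=0.15)

    def test_negative_separation_rejected(self):
        spec = _spec(MediumModel("viscous", eta=0.01), n_particles=0,
                     n_frames=10)
        with pytest.raises(ValueError):
            simulate_bead_pairs(spec, [-1.0], coupling_amplitude=0.0)


class TestWLC:
    def test_contour_length_by_construction(self):
        chains = simulate_wlc_2d(WLCSpec(16.0, 20.0, 0.1, 20, seed=1))
        for c in chains:
            assert contour_length(c) == pytest.approx(20.0, abs=0.1)

    def test_large_persistence_is_straight(self):
        chains = simulate_wlc_2d(WLCSpec(1e12, 10.0, 0.1, 3, seed=1))
        for c in chains:
            assert np.linalg.norm(c[-1] - c[0]) == pytest.approx(10.0, rel=1e-4)

    def test_mean_square_end_to_end_matches_2d_wlc(self):
        lp, L = 16.0, 20.0
        chains = simulate_wlc_2d(WLCSpec(lp, L, 0.1, 600, seed=4))
        r2 = np.array([np.sum((c[-1] - c[0]) ** 2) for c in chains])
        theory = 4 * lp * L * (1 - (2 * lp / L) * (1 - np.exp(-L / (2 * lp))))
        se = np.std(r2) / np.sqrt(len(r2))
        assert abs(np.mean(r2) - theory) < 3 * se

    def test_invalid_discretization(self):
        with pytest.raises(ValueError):
            WLCSpec(l_P=0.05, L=10.0, ds=0.1)


class TestLengths:
    def test_sample_mean_and_weighted_mean(self):
        mu = 5.0
        s = sample_lengths(mu, 30_000, seed=3)
        assert np.mean(s) == pytest.approx(mu, rel=0.03)
        lw = np.sum(s ** 2) / np.sum(s)
        assert lw == pytest.approx(2 * mu, rel=0.05)

    def test_reproducible(self):
        assert np.array_equal(sample_lengths(3.0, 100, seed=8),
                              sample_lengths(3.0, 100, seed=8))

    def test_errors(self):
        with pytest.raises(ValueError):
            sample_lengths(-1.0, 10)
        with pytest.raises(ValueError):
            sample_lengths(1.0, 0)


class TestRenderedImages:
    def test_single_line_peak_height(self):
        img, truth = render_bundle_image([1], i_single=7.0, background=2.0)
        assert img.max() == pytest.approx(2.0 + 7.0, rel=1e-6)
        grid = ImageGrid(img, truth.pixel_size)
        prof = extract_line_profile(grid, (0, 128), (255, 128), width=10)
        ba = bundle_parameter(prof, i_single=7.0)
        assert len(ba.n_B_per_peak) == 1
        assert ba.n_B_per_peak[0] == pytest.approx(1.0, rel=0.05)

    def test_intensity_linear_in_multiplicity(self):
        img1, _ = render_bundle_image([10], i_single=1.0, background=0.0)
        img3, _ = render_bundle_image([30], i_single=1.0, background=0.0)
        assert np.allclose(img3, 3 * img1, rtol=1e-9)

    def test_background_only_has_no_peaks(self):
        img, truth = render_bundle_image([], background=5.0)
        grid = ImageGrid(img, truth.pixel_size)
        prof = extract_line_profile(grid, (0, 128), (255, 128), width=5)
        with pytest.raises(ValueError):
            bundle_parameter(prof, i_single=1.0)

    def test_too_close_lines_rejected(self):
        with pytest.raises(ValueError):
            render_bundle_image([1] * 60, psf_sigma=1.0, shape=(64, 64),
                                pixel_size=0.1)

    def test_aster_truth_geometry(self):
        img, truth = render_aster_image(12, radius_um=1.0,
                                        field_size_um=51.2, seed=2)
        assert truth.total_area_um2 == pytest.approx(12 * np.pi, rel=1e-9)
        assert len(truth.centers_um) == 12
        # pairwise spacing respects the placement constraint
        from scipy.spatial.distance import pdist
        assert pdist(truth.centers_um).min() >= 2.2 * 2.0

    def test_aster_intensity_linear_in_area(self):
        img1, t1 = render_aster_image(1, radius_um=1.0, seed=3,
                                      background=0.0, amplitude=10.0)
        img2, t2 = render_aster_image(1, radius_um=2.0, seed=3,
                                      background=0.0, amplitude=10.0)
        assert (img2.sum() / img1.sum()
                == pytest.approx(t2.total_area_um2 / t1.total_area_um2,
                                 rel=0.05))

    def test_blank_field(self):
        img, truth = render_aster_image(0, seed=1)
        assert np.all(img == img.flat[0])
        assert truth.total_area_um2 == 0.0

    def test_overcrowded_field_rejected(self):
        with pytest.raises(ValueError):
            render_aster_image(500, radius_um=5.0, field_size_um=30.0,
                               max_tries=500)


class TestDeterminism:
    def test_bead_bit_identical(self):
        spec = _spec(MediumModel("kelvin_voigt", G0=0.04, eta=0.005),
                     n_particles=5, n_frames=200, seed=42)
        e1, e2 = simulate_bead(spec), simulate_bead(spec)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_images_bit_identical(self):
        i1, _ = render_aster_image(5, seed=9, noise_sigma=5.0)
        i2, _ = render_aster_image(5, seed=9, noise_sigma=5.0)
        assert np.array_equal(i1, i2)
        b1, _ = render_bundle_image([3, 4], poisson_noise=True, seed=9)
        b2, _ = render_bundle_image([3, 4], poisson_noise=True, seed=9)
        assert np.array_equal(b1, b2)
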