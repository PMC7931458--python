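"""Projector, acquisition simulation and MLEM oracles."""

import numpy as np
import pytest

from munet import petsim as ps


class TestBlur:
    def test_zero_fwhm_is_identity(self, rng):
        img = rng.random((8, 8, 8))
        assert np.array_equal(ps.blur_psf(img, 0.0, (2, 2, 2)), img)

    def test_impulse_response_fwhm(self):
        """4.5 mm FWHM at 2.25 mm voxels -> measured FWHM = 2 voxels +-5%."""
        img = np.zeros((33, 33, 33))
        img[16, 16, 16] = 1.0
        out = ps.blur_psf(img, 4.5, (2.25, 2.25, 2.25))
        prof = out[16, 16, :]
        half = prof.max() / 2
        above = np.where(prof >= half)[0]
        # refine by linear interpolation at the half-maximum crossings
        lo, hi = above[0], above[-1]
        f_lo = lo - 1 + (half - prof[lo - 1]) / (prof[lo] - prof[lo - 1])
        f_hi = hi + (prof[hi] - half) / (prof[hi] - prof[hi + 1])
        fwhm_vox = f_hi - f_lo
        assert fwhm_vox == pytest.approx(2.0, rel=0.05)

    def test_intensity_preserved_interior(self, rng):
        img = np.zeros((24, 24, 24))
        img[8:16, 8:16, 8:16] = rng.random((8, 8, 8))
        out = ps.blur_psf(img, 4.0, (2, 2, 2))
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)

    def test_constant_unchanged_interior(self):
        img = np.ones((24, 24, 24))
        out = ps.blur_psf(img, 4.0, (2, 2, 2))
        assert np.allclose(out[8:-8, 8:-8, 8:-8], 1.0, atol=1e-8)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            ps.blur_psf(np.ones((4, 4, 4)), -1.0, (2, 2, 2))


class TestProjector:
    def test_zero_image_zero_sinogram(self, small_geometry):
        img = np.zeros(small_geometry.image_shape)
        assert np.all(ps.forward_project(img, small_geometry) == 0)

    def test_linearity(self, small_geometry, rng):
        img = rng.random(small_geometry.image_shape)
        s1 = ps.forward_project(img, small_geometry)
        s2 = ps.forward_project(2 * img, small_geometry)
        assert np.allclose(s2, 2 * s1, rtol=1e-12)

    def test_disc_chord_lengths(self):
        """Line integrals of a uniform disc match 2*sqrt(R^2-s^2) within 2%.

        The disc is rasterized with per-pixel area weights (8x8
        supersampling) so the comparison probes the projector rather
        than the jagged pixel boundary.
        """
        n, v, radius = 64, 2.0, 40.0
        ss = 8
        c = (np.arange(n * ss) - (n * ss - 1) / 2) * (v / ss)
        yy, xx = np.meshgrid(c, c, indexing="ij")
        fine = ((yy**2 + xx**2) <= radius**2).astype(float)
        disc = fine.reshape(n, ss, n, ss).mean(axis=(1, 3))[None]
        geom = ps.default_geometry((1, n, n), (v, v, v), n_angles=48)
        sino = ps.forward_project(disc, geom)[0]
        s = (np.arange(geom.n_radial_bins) - (geom.n_radial_bins - 1) / 2) \
            * geom.bin_size_mm
        chord = 2 * np.sqrt(np.maximum(radius**2 - s**2, 0))
        sel = np.abs(s) < 0.7 * radius  # away from the tangent singularity
        assert np.all(np.abs(sino[:, sel] - chord[sel]) / chord[sel] < 0.02)

    def test_adjointness(self, small_geometry, rng):
        f = rng.random(small_geometry.image_shape)
        g = rng.random(small_geometry.sino_shape)
        lhs = np.sum(ps.forward_project(f, small_geometry) * g)
        rhs = np.sum(f * ps.back_project(g, small_geometry))
        assert abs(lhs - rhs) / abs(lhs) < 1e-8

    def test_adjointness_with_attenuation(self, small_geometry, rng):
        mu = np.zeros(small_geometry.image_shape)
        mu[:, 10:20, 10:20] = 0.0975
        f = rng.random(small_geometry.image_shape)
        g = rng.random(small_geometry.sino_shape)
        lhs = np.sum(ps.forward_project(f, small_geometry, mu) * g)
        rhs = np.sum(f * ps.back_project(g, small_geometry, mu))
        assert abs(lhs - rhs) / abs(lhs) < 1e-8

    def test_zero_sinogram_backprojects_to_zero(self, small_geometry):
        assert np.all(ps.back_project(np.zeros(small_geometry.sino_shape),
                                      small_geometry) == 0)

    def test_sensitivity_positive_in_fov(self, small_geometry):
        sens = ps.back_project(np.ones(small_geometry.sino_shape), small_geometry)
        nz, ny, nx = small_geometry.image_shape
        assert np.all(sens[:, ny // 4:-ny // 4, nx // 4:-nx // 4] > 0)

    def test_shape_mismatch_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            ps.forward_project(np.ones((4, 4, 4)), small_geometry)

    def test_radial_coverage_invariant(self):
        with pytest.raises(ValueError, match="diagonal"):
            ps.ProjectionGeometry(n_angles=8, n_radial_bins=10, n_slices=2,
                                  bin_size_mm=2.0, image_shape_2d=(32, 32),
                                  voxel_size_mm=(2.0, 2.0, 2.0))


class TestSimulate:
    def test_background_fractions_exact(self, small_phantom, small_geometry):
        cfg = ps.CountConfig(total_counts=100_000, seed=3)
        sino = ps.simulate_prompts(small_phantom.tau, small_geometry,
                                   small_phantom.mu_map, cfg)
        assert sino.randoms_expected.sum() / cfg.total_counts == pytest.approx(0.26)
        assert sino.scatter_expected.sum() / cfg.total_counts == pytest.approx(0.28)

    def test_total_prompts_poisson_mean(self, small_phantom, small_geometry):
        cfg = ps.CountConfig(total_counts=50_000, seed=5)
        sinos = ps.simulate_realizations(small_phantom.tau, small_geometry,
                                         small_phantom.mu_map, cfg, 10)
        totals = [s.prompts.sum() for s in sinos]
        # mean of 10 Poisson totals within 3 standard errors
        se = np.sqrt(cfg.total_counts / 10)
        assert abs(np.mean(totals) - cfg.total_counts) < 3 * se

    def test_prompts_integer_nonnegative(self, small_phantom, small_geometry):
        cfg = ps.CountConfig(total_counts=10_000, seed=1)
        sino = ps.simulate_prompts(small_phantom.tau, small_geometry,
                                   small_phantom.mu_map, cfg)
        assert np.all(sino.prompts >= 0)
        assert np.all(sino.prompts == np.round(sino.prompts))
        assert np.all(sino.att_factors > 0) and np.all(sino.att_factors <= 1)

    def test_zero_activity_randoms_only(self, small_geometry):
        cfg = ps.CountConfig(total_counts=10_000, seed=2)
        tau = np.zeros(small_geometry.image_shape)
        sino = ps.simulate_prompts(tau, small_geometry, None, cfg)
        assert sino.scatter_expected.sum() == 0
        assert sino.randoms_expected.sum() == pytest.approx(0.26 * 10_000)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            ps.CountConfig(total_counts=1000, randoms_fraction=0.6,
                           scatter_fraction=0.5)


def _consistent_sinogram(geom, theta_star, rm=None, rho_level=0.0):
    """Noise-free m = X H theta* + rho supported inside the FOV."""
    blurred = ps.blur_psf(theta_star, rm, geom.voxel_size_mm) if rm else theta_star
    trues = ps.forward_project(blurred, geom)
    rho = np.full(geom.sino_shape, rho_level)
    return ps.Sinogram(prompts=trues + rho, randoms_expected=rho,
                       scatter_expected=np.zeros(geom.sino_shape),
                       att_factors=np.ones(geom.sino_shape), geometry=geom,
                       total_counts=int(trues.sum()))


class TestMLEM:
    def test_fixed_point_on_consistent_data(self, small_geometry):
        """Noise-free m = X theta* + rho with init theta*: update factor 1."""
        rng = np.random.default_rng(0)
        theta = np.full(small_geometry.image_shape, 0.2)
        theta[:, 8:24, 8:24] += rng.random((theta.shape[0], 16, 16))
        sino = _consistent_sinogram(small_geometry, theta, rho_level=0.01)
        res = ps.mlem(sino, n_iter=1, init=theta)
        sens = ps.back_project(np.ones(small_geometry.sino_shape), small_geometry)
        fov = sens > 1e-12
        assert np.allclose(res.image[fov], theta[fov], rtol=1e-8)

    def test_iterates_nonnegative(self, small_phantom, small_geometry):
        cfg = ps.CountConfig(total_counts=20_000, seed=9)
        sino = ps.simulate_prompts(small_phantom.tau, small_geometry,
                                   small_phantom.mu_map, cfg)
        res = ps.mlem(sino, n_iter=5, checkpoints=(1, 2, 3, 4, 5))
        for k, img in res.history.items():
            assert img.min() >= 0

    def test_count_conservation_rho_zero(self, small_geometry):
        """sum_j sens_j theta_j = sum_i m_i after every iteration (rho = 0)."""
        rng = np.random.default_rng(3)
        theta = np.zeros(small_geometry.image_shape)
        theta[:, 10:22, 10:22] = rng.random((theta.shape[0], 12, 12)) + 0.2
        trues = ps.forward_project(ps.blur_psf(theta, 4.5,
                                               small_geometry.voxel_size_mm),
                                   small_geometry)
        m = rng.poisson(trues * (20_000 / trues.sum())).astype(float)
        sino = ps.Sinogram(prompts=m, randoms_expected=np.zeros_like(m),
                           scatter_expected=np.zeros_like(m),
                           att_factors=np.ones_like(m), geometry=small_geometry,
                           total_counts=int(m.sum()))
        sens = ps.back_project(np.ones(small_geometry.sino_shape), small_geometry)
        for k in (1, 2, 5):
            res = ps.mlem(sino, n_iter=k)
            assert (sens * res.image).sum() == pytest.approx(m.sum(), rel=1e-8)

    def test_loglik_monotone(self, small_geometry, small_phantom):
        cfg = ps.CountConfig(total_counts=20_000, seed=4)
        sino = ps.simulate_prompts(small_phantom.tau, small_geometry,
                                   small_phantom.mu_map, cfg)
        res = ps.mlem(sino, n_iter=8, checkpoints=range(1, 9))
        lls = []
        for k in sorted(res.history):
            proj = ps.forward_project(res.history[k], small_geometry) \
                * sino.att_factors + sino.background
            lls.append(ps.poisson_loglik(sino.prompts, proj))
        assert np.all(np.diff(lls) >= -1e-6 * np.abs(lls[0]))

    def test_rm_lowers_variance_across_realizations(self, small_phantom,
                                                    small_geometry):
        """RM reconstructions are smoother: lower voxel variance at matched
        iteration than without RM."""
        cfg = ps.CountConfig(total_counts=50_000, seed=6)
        sinos = ps.simulate_realizations(small_phantom.tau, small_geometry,
                                         small_phantom.mu_map, cfg, 6)
        plain = ps.mlem_batch(sinos, n_iter=30, dtype=np.float32)
        rm = ps.mlem_batch(sinos, rm_fwhm_mm=4.5, n_iter=30, dtype=np.float32)
        var_plain = plain.image.var(axis=0).sum()
        var_rm = rm.image.var(axis=0).sum()
        assert var_rm < var_plain

    def test_default_iteration_counts(self):
        geom = ps.default_geometry((2, 16, 16), (2, 2, 2), n_angles=8)
        sino = _consistent_sinogram(geom, np.ones(geom.image_shape))
        assert ps.mlem(sino, n_iter=None).n_iterations == 100

    def test_bad_init_rejected(self, small_geometry):
        sino = _consistent_sinogram(small_geometry,
                                    np.ones(small_geometry.image_shape))
        with pytest.raises(ValueError, match="init"):
            ps.mlem(sino, n_iter=1, init=np.zeros(small_geometry.image_shape))
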