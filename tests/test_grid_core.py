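"""Finite-difference primitives: gradients, curvature, reinitialization, masks."""

import numpy as np
import pytest

from tumorseg3d import (
    DataQualityError,
    EmptyFrontError,
    GridError,
    ImageVolume,
    LevelSetField,
    band_mask,
    extract_mask,
    front_points,
    gradient_magnitude,
    mean_curvature,
    reinitialize,
    sphere_sdf,
)
from conftest import brute_force_signed_distance


class TestImageVolume:
    def test_rejects_non_finite_data(self):
        data = np.ones((8, 8, 8))
        data[3, 3, 3] = np.nan
        with pytest.raises(DataQualityError):
            ImageVolume(data, (1, 1, 1))

    @pytest.mark.parametrize("spacing", [(0, 1, 1), (1, -2, 1)])
    def test_rejects_nonpositive_spacing(self, spacing):
        with pytest.raises(GridError):
            ImageVolume(np.ones((8, 8, 8)), spacing)

    def test_rejects_tiny_dimensions(self):
        with pytest.raises(GridError):
            ImageVolume(np.ones((3, 8, 8)), (1, 1, 1))


class TestGradientMagnitude:
    def test_constant_image_is_zero(self, unit_volume):
        assert gradient_magnitude(unit_volume, 0.0).max() == 0.0

    def test_linear_ramp(self):
        x = np.arange(12, dtype=float)
        vol = ImageVolume(np.broadcast_to(2 * x[:, None, None], (12, 12, 12)).copy(),
                          (1, 1, 1))
        g = gradient_magnitude(vol, 0.0)
        assert np.allclose(g[1:-1], 2.0)

    def test_gaussian_blob_matches_analytic_gradient(self):
        # I = exp(-r^2 / 2s^2): |grad I| = (r/s^2) I, checked away from borders
        n, s = 32, 5.0
        x, y, z = np.meshgrid(*(np.arange(n, dtype=float),) * 3, indexing="ij")
        r2 = (x - 15.5) ** 2 + (y - 15.5) ** 2 + (z - 15.5) ** 2
        img = np.exp(-r2 / (2 * s * s))
        vol = ImageVolume(img, (1, 1, 1))
        g = gradient_magnitude(vol, 0.0)
        analytic = np.sqrt(r2) / (s * s) * img
        inner = (slice(4, -4),) * 3
        sel = analytic[inner] > 1e-3
        rel = np.abs(g[inner] - analytic[inner])[sel] / analytic[inner][sel]
        assert rel.max() < 0.02

    def test_physical_spacing_respected(self):
        # same array, doubled z spacing -> z-gradient halves
        rng = np.random.default_rng(0)
        data = rng.normal(size=(10, 10, 10)).cumsum(axis=2)
        g1 = gradient_magnitude(ImageVolume(data, (1, 1, 1)), 0.0)
        g2 = gradient_magnitude(ImageVolume(data, (1, 1, 2)), 0.0)
        assert g2.mean() < g1.mean()


class TestMeanCurvature:
    def test_plane_has_zero_curvature(self):
        x = np.arange(16, dtype=float)
        phi = np.broadcast_to(x[:, None, None] - 5.0, (16, 16, 16)).copy()
        kappa = mean_curvature(LevelSetField(phi, (1, 1, 1)))
        near = np.abs(phi) < 1.5
        assert np.abs(kappa[near]).max() < 1e-6

    def test_sphere_curvature_is_two_over_r(self, sphere_field):
        kappa = mean_curvature(sphere_field)
        surf = np.abs(sphere_field.phi) < 0.5
        assert kappa[surf].mean() == pytest.approx(0.2, rel=0.02)

    def test_ellipsoid_matches_refined_stencil_oracle(self):
        # oracle: same divergence formula on a 2x finer grid, sampled at
        # 20 surface points of the coarse grid
        def phi_fn(x, y, z):
            return np.sqrt((x - 24) ** 2 / 1.0 + (y - 24) ** 2 / 2.25
                           + (z - 24) ** 2 / 4.0) - 8.0

        n = 48
        xs = np.arange(n, dtype=float)
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        coarse = LevelSetField(phi_fn(X, Y, Z), (1, 1, 1))
        kappa_c = mean_curvature(coarse)

        xf = np.arange(0, n, 0.5)
        Xf, Yf, Zf = np.meshgrid(xf, xf, xf, indexing="ij")
        fine = LevelSetField(phi_fn(Xf, Yf, Zf), (0.5, 0.5, 0.5))
        kappa_f = mean_curvature(fine)

        surf_idx = np.argwhere(np.abs(coarse.phi) < 0.3)[:20]
        for i, j, k in surf_idx:
            oracle = kappa_f[2 * i, 2 * j, 2 * k]
            assert kappa_c[i, j, k] == pytest.approx(oracle, rel=0.05)

    def test_sphere_curvature_error_halves_with_resolution(self):
        # median pointwise |kappa - 2/rho| over surface voxels
        errs = []
        for n, h in [(24, 2.0), (48, 1.0)]:
            c = (n - 1) * h / 2
            fld = sphere_sdf((n, n, n), (h, h, h), (c, c, c), 16.0)
            kappa = mean_curvature(fld)
            x = np.arange(n) * h
            X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
            rho = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2)
            surf = np.abs(fld.phi) < h / 2
            errs.append(np.median(np.abs(kappa[surf] - 2.0 / rho[surf])))
        assert errs[1] <= errs[0] / 2 + 1e-12


class TestReinitialize:
    def test_idempotent_on_sphere_sdf(self, sphere_field):
        out = reinitialize(sphere_field)
        band = band_mask(out)
        assert np.abs(out.phi - sphere_field.phi)[band].max() < 0.1

    def test_rescaled_sdf_recovers_unit_gradient(self, sphere_field):
        scaled = LevelSetField(3.0 * sphere_field.phi, sphere_field.spacing)
        out = reinitialize(scaled)
        band = band_mask(out)
        assert np.abs(out.phi - sphere_field.phi)[band].max() < 0.1

    def test_blob_matches_exhaustive_distance_oracle(self, blob_field):
        out = reinitialize(blob_field)
        oracle = brute_force_signed_distance(
            blob_field.phi, blob_field.spacing, front_points(blob_field)
        )
        band = band_mask(out)
        assert np.abs(out.phi - oracle)[band].max() < 0.5

    def test_double_application_is_stable(self, blob_field):
        once = reinitialize(blob_field)
        twice = reinitialize(once)
        band = band_mask(twice)
        assert np.abs(twice.phi - once.phi)[band].max() < 0.1

    def test_sign_pattern_preserved(self, blob_field):
        out = reinitialize(blob_field)
        assert np.array_equal(out.phi < 0, blob_field.phi < 0)

    def test_unit_gradient_in_band(self, blob_field):
        # |grad phi| ~ 1 in the band; the interior medial axis (where any
        # distance function kinks) is excluded from the strict check
        out = reinitialize(blob_field)
        gx, gy, gz = np.gradient(out.phi, *out.spacing)
        gn = np.sqrt(gx**2 + gy**2 + gz**2)
        band = band_mask(out)
        assert np.abs(1 - gn[band]).mean() < 0.05
        exterior = band & (out.phi > 1.0)
        assert (gn[exterior] > 0.95).mean() > 0.99

    def test_uniform_sign_raises(self):
        with pytest.raises(EmptyFrontError):
            reinitialize(LevelSetField(np.ones((8, 8, 8)), (1, 1, 1)))


class TestExtractMask:
    def test_all_positive_gives_empty_mask(self):
        fld = LevelSetField(np.ones((8, 8, 8)), (1, 1, 1))
        assert not extract_mask(fld).data.any()

    def test_all_negative_gives_full_mask(self):
        fld = LevelSetField(-np.ones((8, 8, 8)), (1, 1, 1))
        assert extract_mask(fld).data.all()

    def test_sphere_voxel_count_matches_brute_force(self):
        fld = sphere_sdf((16, 16, 16), (1, 1, 1), (7.5, 7.5, 7.5), 5.0)
        mask = extract_mask(fld)
        ii, jj, kk = np.meshgrid(*(np.arange(16),) * 3, indexing="ij")
        inside = ((ii - 7.5) ** 2 + (jj - 7.5) ** 2 + (kk - 7.5) ** 2) < 25.0
        assert mask.data.sum() == inside.sum()

    def test_mask_stable_under_reinitialization(self, blob_field):
        before = extract_mask(blob_field).data
        after = extract_mask(reinitialize(blob_field)).data
        changed = before != after
        # only voxels within half a voxel of the front may flip
        assert not changed.any() or np.abs(blob_field.phi[changed]).max() <= 0.5
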