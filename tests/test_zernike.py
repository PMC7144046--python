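"""Zernike basis, elevation fitting, pupil rescaling and RMS groups."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icrsplan.zernike import (
    ElevationMap,
    FitError,
    ZernikeCoefficients,
    elevation_to_wavefront,
    fit_elevation,
    index_to_nm,
    n_terms,
    osa_index,
    reconstruct,
    rescale_pupil,
    rms_groups,
    zernike_term,
)


def square_grid(halfwidth=5.0, n=101):
    xs = np.linspace(-halfwidth, halfwidth, n)
    return xs, np.meshgrid(xs, xs)


def map_from_coeffs(c, halfwidth=5.0, n=101):
    xs, (x, y) = square_grid(halfwidth, n)
    return ElevationMap(xs, xs, reconstruct(c, x, y), diameter_mm=2 * halfwidth)


class TestBasis:
    @pytest.mark.parametrize(
        "n, m, rho, theta, expected",
        [
            (0, 0, 0.37, 2.1, 1.0),                      # piston is constant
            (1, 1, 1.0, 0.0, 2.0),                       # sqrt(4)·rho·cos
            (2, 0, 1.0, 0.4, math.sqrt(3.0)),            # sqrt(3)(2rho²−1)
            (2, -2, 1.0, np.pi / 4, math.sqrt(6.0)),     # sqrt(6)rho²sin2θ
            (3, 1, 0.5, 0.0, math.sqrt(8.0) * (3 * 0.125 - 2 * 0.5)),
        ],
    )
    def test_analytic_values(self, n, m, rho, theta, expected):
        assert zernike_term(n, m, rho, theta) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n, m", [(2, 1), (1, -2), (3, 4), (-1, 0)])
    def test_invalid_indices_rejected(self, n, m):
        with pytest.raises(ValueError):
            zernike_term(n, m, 0.5, 0.0)

    def test_osa_index_roundtrip(self):
        for j in range(n_terms(7)):
            n, m = index_to_nm(j)
            assert osa_index(n, m) == j
        assert n_terms(7) == 36

    def test_orthonormality_on_dense_disk(self):
        """Basis Gram matrix over the unit disk is the identity."""
        from conftest import disk_gram

        gram = disk_gram(7, 512)
        assert np.abs(gram - np.eye(36)).max() < 1e-3


class TestFit:
    def test_recovers_single_term(self):
        for j in (4, 7, 12, 35):
            v = np.zeros(36)
            v[j] = 1.5
            emap = map_from_coeffs(ZernikeCoefficients(v, 8.0))
            got = fit_elevation(emap, 8.0, 7)
            assert got.values[j] == pytest.approx(1.5, abs=1e-6)
            others = np.delete(got.values, j)
            assert np.abs(others).max() < 1e-6

    def test_zero_map_and_vector_length(self):
        xs, _ = square_grid()
        emap = ElevationMap(xs, xs, np.zeros((101, 101)), diameter_mm=10)
        got = fit_elevation(emap, 8.0, 7)
        assert len(got) == 36
        assert np.abs(got.values).max() < 1e-12

    def test_round_trip_random_vector(self, rng):
        c = ZernikeCoefficients(rng.normal(0, 1, 36), 8.0)
        got = fit_elevation(map_from_coeffs(c), 8.0, 7)
        assert np.abs(got.values - c.values).max() < 1e-8
        assert got.residual_rms < 1e-8

    def test_parseval_grid_rms_matches_coefficient_norm(self, rng):
        """Surface RMS over the pupil equals the coefficient vector norm."""
        v = rng.normal(0, 1, 36)
        v[:3] = 0.0  # piston/tilt removed
        c = ZernikeCoefficients(v, 8.0)
        xs, (x, y) = square_grid(4.0, 801)
        z = reconstruct(c, x, y)
        inside = np.hypot(x, y) <= 4.0
        grid_rms = np.sqrt(np.nanmean(z[inside] ** 2))
        assert grid_rms == pytest.approx(np.linalg.norm(v), rel=2e-3)

    def test_sparse_sampling_raises(self):
        xs = np.linspace(-5, 5, 9)
        emap = ElevationMap(xs, xs, np.zeros((9, 9)), diameter_mm=10)
        with pytest.raises(FitError):
            fit_elevation(emap, 8.0, 7)

    def test_too_many_missing_raises(self):
        xs, (x, y) = square_grid()
        z = np.zeros_like(x)
        z[x > 0] = np.nan  # half the aperture missing
        emap = ElevationMap(xs, xs, z, diameter_mm=10)
        with pytest.raises(FitError, match="missing"):
            fit_elevation(emap, 8.0, 7)


class TestRescale:
    def test_identity_ratio(self, rng):
        c = ZernikeCoefficients(rng.normal(0, 1, 36), 8.0)
        out = rescale_pupil(c, 8.0)
        assert np.array_equal(out.values, c.values)
        assert out.pupil_diameter_mm == 8.0

    def test_defocus_scaling_with_piston_shift(self):
        v = np.zeros(36)
        v[osa_index(2, 0)] = 1.0
        out = rescale_pupil(ZernikeCoefficients(v, 8.0), 6.0)
        r2 = (6.0 / 8.0) ** 2
        assert out.get(2, 0) == pytest.approx(r2, abs=1e-12)
        assert out.get(0, 0) == pytest.approx(math.sqrt(3) * (r2 - 1), abs=1e-12)

    def test_matches_dense_refit(self, rng):
        """The analytic rescale equals a brute-force refit on the sub-pupil."""
        c = ZernikeCoefficients(rng.normal(0, 1, 36), 8.0)
        out = rescale_pupil(c, 6.0)
        xs, (x, y) = square_grid(4.0, 161)
        z = np.where(np.hypot(x, y) <= 3.0, reconstruct(c, x, y), np.nan)
        refit = fit_elevation(
            ElevationMap(xs, xs, z, diameter_mm=8.0), 6.0, 7
        )
        assert np.abs(out.values - refit.values).max() < 1e-8

    @given(r1=st.floats(0.5, 1.0), r2=st.floats(0.2, 0.5))
    @settings(max_examples=20, deadline=None)
    def test_composition(self, r1, r2):
        rng = np.random.default_rng(7)
        c = ZernikeCoefficients(rng.normal(0, 1, 36), 8.0)
        via = rescale_pupil(rescale_pupil(c, 8.0 * r1), 8.0 * r2)
        direct = rescale_pupil(c, 8.0 * r2)
        assert np.abs(via.values - direct.values).max() < 1e-9

    def test_upscaling_refused(self):
        c = ZernikeCoefficients(np.zeros(36), 6.0)
        with pytest.raises(ValueError, match="extrapolation"):
            rescale_pupil(c, 8.0)


class TestWavefrontAndGroups:
    def test_elevation_to_wavefront_is_scalar_multiply(self, rng):
        a = ZernikeCoefficients(rng.normal(0, 1, 36), 8.0)
        b = ZernikeCoefficients(rng.normal(0, 1, 36), 8.0)
        wa = elevation_to_wavefront(a)
        assert np.allclose(wa.values, a.values * 0.376)
        w_sum = elevation_to_wavefront(
            ZernikeCoefficients(a.values + b.values, 8.0)
        )
        assert np.allclose(
            w_sum.values, wa.values + elevation_to_wavefront(b).values
        )
        assert np.all(elevation_to_wavefront(
            ZernikeCoefficients(np.zeros(36), 8.0)).values == 0)

    def test_single_coma_term_groups(self):
        v = np.zeros(36)
        v[osa_index(3, 1)] = 2.0
        g = rms_groups(ZernikeCoefficients(v, 6.0), 6.0)
        assert g.coma_like == pytest.approx(2.0)
        assert g.hoa == pytest.approx(2.0)
        assert g.spherical_like == 0.0
        assert g.astigmatism == 0.0

    def test_pythagorean_total(self):
        v = np.zeros(36)
        v[osa_index(2, 2)] = 3.0
        v[osa_index(4, 0)] = 4.0
        g = rms_groups(ZernikeCoefficients(v, 6.0), 6.0)
        assert g.total == pytest.approx(5.0)
        assert g.astigmatism == pytest.approx(3.0)
        assert g.spherical_like == pytest.approx(4.0)

    def test_zero_vector_groups(self):
        g = rms_groups(ZernikeCoefficients(np.zeros(36), 6.0), 6.0)
        assert (g.total, g.hoa, g.astigmatism, g.coma_like, g.spherical_like) \
            == (0, 0, 0, 0, 0)

    def test_group_partition_residual_nonnegative(self, rng):
        v = rng.normal(0, 1, 36)
        g = rms_groups(ZernikeCoefficients(v, 6.0), 6.0)
        resid_sq = g.hoa**2 - g.coma_like**2 - g.spherical_like**2
        assert resid_sq >= -1e-12

    def test_rotation_invariance_of_rotational_groups(self, rng):
        """Rotating the surface leaves total/hoa/spherical-like unchanged."""
        c = ZernikeCoefficients(rng.normal(0, 1, 36), 8.0)
        xs, (x, y) = square_grid()
        alpha = np.deg2rad(37.0)
        xr = x * np.cos(alpha) - y * np.sin(alpha)
        yr = x * np.sin(alpha) + y * np.cos(alpha)
        rotated = ElevationMap(xs, xs, reconstruct(c, xr, yr), diameter_mm=10)
        g0 = rms_groups(fit_elevation(map_from_coeffs(c), 8.0, 7), 6.0)
        g1 = rms_groups(fit_elevation(rotated, 8.0, 7), 6.0)
        for attr in ("total", "hoa", "spherical_like", "coma_like"):
            assert getattr(g1, attr) == pytest.approx(getattr(g0, attr), abs=1e-6)

    def test_upscale_request_refused(self):
        with pytest.raises(ValueError):
            rms_groups(ZernikeCoefficients(np.zeros(36), 6.0), 8.0)
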