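"""Fourier-space elasticity: kernel, forward map, regularized inversion."""

import numpy as np
import pytest

from tfmkit import (
    ElasticSubstrate,
    RegularizationChoice,
    VectorField2D,
    finite_thickness_correction,
    forward_displacement,
    fttc_solve,
    gcv_select_lambda,
    greens_tensor_fourier,
    lanczos_filter,
)


def band_limited_traction(n=128, d=1.0, kfrac=0.15, seed=0):
    """Random traction with spectrum confined well below Nyquist."""
    rng = np.random.default_rng(seed)
    k = np.fft.fftfreq(n)
    KX, KY = np.meshgrid(k, k)
    band = np.hypot(KX, KY) < kfrac
    out = []
    for _ in range(2):
        spec = np.zeros((n, n), complex)
        spec[band] = rng.normal(size=band.sum()) + 1j * rng.normal(size=band.sum())
        a = np.fft.ifft2(spec).real
        out.append(100.0 * (a - a.mean()))
    return VectorField2D(out[0], out[1], d, "Pa")


class TestGreensTensor:
    def test_doubling_E_halves_entries(self):
        k = np.array([0.3]), np.array([0.2])
        g1 = greens_tensor_fourier(*k, ElasticSubstrate(10_000, 0.5))
        g2 = greens_tensor_fourier(*k, ElasticSubstrate(20_000, 0.5))
        for a, b in zip(g1, g2):
            assert np.allclose(a, 2 * b)

    def test_inversion_symmetry(self):
        kx = np.array([0.3, -0.3])
        ky = np.array([0.17, -0.17])
        gxx, gxy, gyy = greens_tensor_fourier(kx, ky, ElasticSubstrate())
        assert gxx[0] == pytest.approx(gxx[1])
        assert gxy[0] == pytest.approx(gxy[1])
        assert gyy[0] == pytest.approx(gyy[1])

    def test_positive_semidefinite_and_regular_at_incompressible(self):
        rng = np.random.default_rng(0)
        kx, ky = rng.normal(size=50), rng.normal(size=50)
        gxx, gxy, gyy = greens_tensor_fourier(kx, ky, ElasticSubstrate(nu=0.5))
        assert np.isfinite(gxx).all() and np.isfinite(gyy).all()
        det = gxx * gyy - gxy**2
        assert (det >= -1e-30).all()
        assert (gxx >= 0).all() and (gyy >= 0).all()

    def test_zero_mode_is_zero(self):
        gxx, gxy, gyy = greens_tensor_fourier(np.array([0.0]), np.array([0.0]), ElasticSubstrate())
        assert gxx[0] == gxy[0] == gyy[0] == 0.0

    def test_forward_matches_realspace_boussinesq_oracle(self):
        """Discrete forward solution agrees with direct real-space
        convolution of the Boussinesq surface kernel within 2% (smooth
        force-free source; scored over an annulus away from it)."""
        sub = ElasticSubstrate(20_000, 0.5)
        E, nu = sub.E, sub.nu
        n, d, sigma = 256, 1.0, 2.0
        x = np.arange(n) * d
        xx, yy = np.meshgrid(x, x)
        c = (n // 2) * d
        tx = 100.0 * (
            np.exp(-(((xx - (c - 6)) ** 2 + (yy - c) ** 2) / (2 * sigma**2)))
            - np.exp(-(((xx - (c + 6)) ** 2 + (yy - c) ** 2) / (2 * sigma**2)))
        )
        tr = VectorField2D(tx, np.zeros_like(tx), d, "Pa")
        u = forward_displacement(tr, sub)

        r0 = np.hypot(xx - c, yy - c)
        ann = (r0 > 18) & (r0 < 40)
        iy, ix = np.nonzero(ann)
        sy, sx = np.nonzero(np.abs(tx) > 1e-3 * np.abs(tx).max())
        tvals = tx[sy, sx]
        ux_o = np.zeros(len(iy))
        uy_o = np.zeros(len(iy))
        for k in range(len(sy)):
            dx = x[ix] - x[sx[k]]
            dy = x[iy] - x[sy[k]]
            r = np.hypot(dx, dy)
            ux_o += (1 + nu) / (np.pi * E * r**3) * ((1 - nu) * r**2 + nu * dx**2) * tvals[k] * d * d
            uy_o += (1 + nu) / (np.pi * E * r**3) * (nu * dx * dy) * tvals[k] * d * d
        num = np.sqrt(((u.u[iy, ix] - ux_o) ** 2 + (u.v[iy, ix] - uy_o) ** 2).sum())
        den = np.sqrt((ux_o**2 + uy_o**2).sum())
        assert num / den < 0.02


class TestFiniteThickness:
    def test_large_thickness_matches_half_space(self):
        kx, ky = np.array([0.1, 0.5]), np.array([0.2, 0.1])
        half = greens_tensor_fourier(kx, ky, ElasticSubstrate())
        thick = finite_thickness_correction(kx, ky, 1e4, ElasticSubstrate())
        for a, b in zip(half, thick):
            assert np.allclose(a, b, rtol=1e-2)

    def test_monotone_in_thickness(self):
        kx, ky = np.array([0.2]), np.array([0.0])
        prev = 0.0
        for h in (2.0, 5.0, 10.0, 50.0):
            gxx, _, _ = finite_thickness_correction(kx, ky, h, ElasticSubstrate())
            assert gxx[0] > prev
            prev = gxx[0]

    def test_short_wavelength_limit(self):
        kx, ky = np.array([5.0]), np.array([0.0])
        half = greens_tensor_fourier(kx, ky, ElasticSubstrate())
        thin = finite_thickness_correction(kx, ky, 10.0, ElasticSubstrate())  # k·h = 50
        assert thin[0][0] == pytest.approx(half[0][0], rel=1e-6)

    def test_nonpositive_thickness_raises(self):
        with pytest.raises(ValueError):
            finite_thickness_correction(np.array([0.1]), np.array([0.1]), 0.0, ElasticSubstrate())


class TestForwardInverse:
    def test_zero_traction_zero_displacement(self, substrate):
        t = VectorField2D(np.zeros((32, 32)), np.zeros((32, 32)), 1.0, "Pa")
        u = forward_displacement(t, substrate)
        assert np.allclose(u.u, 0) and np.allclose(u.v, 0)

    def test_linearity(self, substrate):
        t = band_limited_traction()
        u1 = forward_displacement(t, substrate)
        u2 = forward_displacement(t.scaled(2.0), substrate)
        assert np.allclose(u2.u, 2 * u1.u, atol=1e-12)

    def test_round_trip_band_limited(self, substrate):
        """Unregularized inversion of the exact forward map recovers a
        band-limited traction to < 1%."""
        t = band_limited_traction()
        u = forward_displacement(t, substrate, pad=False)
        rec = fttc_solve(u, substrate, RegularizationChoice("manual", lam=1e-20), pad=False)
        rel = np.sqrt(((rec.u - t.u) ** 2 + (rec.v - t.v) ** 2).sum() / ((t.u**2 + t.v**2).sum()))
        assert rel < 0.01

    def test_zero_displacement_zero_traction(self, substrate):
        u = VectorField2D(np.zeros((32, 32)), np.zeros((32, 32)), 1.0, "um")
        t = fttc_solve(u, substrate, RegularizationChoice("manual", lam=1e-12))
        assert np.allclose(t.u, 0) and np.allclose(t.v, 0)

    def test_solver_linearity_in_displacement(self, substrate):
        t = band_limited_traction(seed=3)
        u = forward_displacement(t, substrate)
        lam = 1e-10
        r1 = fttc_solve(u, substrate, RegularizationChoice("manual", lam=lam))
        r2 = fttc_solve(u.scaled(3.0), substrate, RegularizationChoice("manual", lam=lam))
        assert np.allclose(r2.u, 3 * r1.u, atol=1e-9)

    def test_large_lambda_kills_traction(self, substrate):
        t = band_limited_traction()
        u = forward_displacement(t, substrate)
        rec = fttc_solve(u, substrate, RegularizationChoice("manual", lam=1e6))
        assert np.abs(rec.u).max() < 1e-6 * np.abs(t.u).max()

    def test_traction_norm_monotone_in_lambda(self, substrate):
        t = band_limited_traction(seed=5)
        u = forward_displacement(t, substrate)
        norms = []
        for lam in np.logspace(-14, -4, 6):
            rec = fttc_solve(u, substrate, RegularizationChoice("manual", lam=lam))
            norms.append(np.hypot(rec.u, rec.v).sum())
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_units_audit_E_u_rescaling(self):
        """Scaling E by c and u by 1/c leaves t/c invariant: with E in Pa
        and u in µm the output is in Pa."""
        t = band_limited_traction(seed=7)
        sub1 = ElasticSubstrate(20_000, 0.5)
        sub2 = ElasticSubstrate(40_000, 0.5)
        u1 = forward_displacement(t, sub1)
        u2 = forward_displacement(t, sub2)
        assert np.allclose(u2.u, 0.5 * u1.u, atol=1e-15)
        rec1 = fttc_solve(u1, sub1, RegularizationChoice("manual", lam=1e-12))
        lam2 = 1e-12 / 4  # lambda has units of G^2 ~ 1/E^2
        rec2 = fttc_solve(u2, sub2, RegularizationChoice("manual", lam=lam2))
        assert np.allclose(rec1.u, rec2.u, rtol=1e-6, atol=1e-9)

    def test_pixel_units_rejected(self, substrate):
        u = VectorField2D(np.ones((16, 16)), np.ones((16, 16)), 1.0, "px")
        with pytest.raises(ValueError):
            fttc_solve(u, substrate)

    def test_nonfinite_displacement_rejected(self, substrate):
        arr = np.ones((16, 16))
        bad = arr.copy()
        bad[3, 3] = np.nan
        with pytest.raises(ValueError):
            fttc_solve(VectorField2D(bad, arr, 1.0, "um"), substrate)


class TestGCV:
    def test_curve_has_one_value_per_grid_point(self, substrate):
        t = band_limited_traction(seed=1)
        u = forward_displacement(t, substrate)
        grid = np.logspace(-16, -6, 12)
        lam, curve = gcv_select_lambda(u, substrate, grid)
        assert curve.shape == (12,)
        assert lam in grid

    def test_noise_free_picks_low_edge_and_noise_increases_lambda(self, substrate, rng):
        t = band_limited_traction(seed=2)
        u = forward_displacement(t, substrate)
        grid = np.logspace(-16, -4, 20)
        with pytest.warns(UserWarning):
            lam_clean, _ = gcv_select_lambda(u, substrate, grid)
        noisy = u.copy()
        scale = np.abs(u.u).max()
        noisy.u = u.u + rng.normal(0, 0.3 * scale, u.shape)
        noisy.v = u.v + rng.normal(0, 0.3 * scale, u.shape)
        lam_noisy, _ = gcv_select_lambda(noisy, substrate, grid)
        assert lam_clean <= grid[1]
        assert lam_noisy > lam_clean

    def test_boundary_minimum_warns(self, substrate):
        t = band_limited_traction(seed=4)
        u = forward_displacement(t, substrate)
        with pytest.warns(UserWarning, match="edge"):
            gcv_select_lambda(u, substrate, np.logspace(-16, -12, 10))


class TestLanczos:
    def test_exponent_zero_is_identity(self):
        f = band_limited_traction(seed=8)
        out = lanczos_filter(f, 0)
        assert np.array_equal(out.u, f.u)

    def test_constant_field_unchanged(self):
        f = VectorField2D(np.full((32, 32), 5.0), np.full((32, 32), -2.0), 1.0, "Pa")
        out = lanczos_filter(f, 2.0)
        assert np.allclose(out.u, 5.0) and np.allclose(out.v, -2.0)

    @pytest.mark.parametrize("exponent", [1.0, 2.0, 4.0])
    def test_power_never_increases(self, rng, exponent):
        f = VectorField2D(rng.normal(size=(64, 64)), rng.normal(size=(64, 64)), 1.0, "Pa")
        out = lanczos_filter(f, exponent)
        assert (out.u**2 + out.v**2).sum() <= (f.u**2 + f.v**2).sum()

    def test_negative_exponent_raises(self):
        f = VectorField2D(np.zeros((8, 8)), np.zeros((8, 8)), 1.0, "Pa")
        with pytest.raises(ValueError):
            lanczos_filter(f, -1.0)
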