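"""Traction cytometry: Fourier kernel, inversions, mechanics metrics."""

import numpy as np
import pytest

from cytomech import fttm, piv, synthgen
from cytomech.fttm import _greens_fourier


def random_periodic_traction(shape, spacing, seed=0):
    rng = np.random.default_rng(seed)
    tx = rng.normal(size=shape)
    ty = rng.normal(size=shape)
    return fttm.TractionField(tx - tx.mean(), ty - ty.mean(), spacing)


class TestKernel:
    def test_positive_definite_on_random_wavevectors(self):
        rng = np.random.default_rng(0)
        for nu in (0.1, 0.3, 0.48):
            kx = rng.uniform(-5, 5, 200)
            ky = rng.uniform(-5, 5, 200)
            k2 = kx**2 + ky**2
            k = np.sqrt(k2)
            keep = k > 1e-9
            pref = 2 * (1 + nu) / (1300.0 * k[keep] ** 3)
            gxx = pref * ((1 - nu) * k2[keep] + nu * ky[keep] ** 2)
            gyy = pref * ((1 - nu) * k2[keep] + nu * kx[keep] ** 2)
            gxy = -pref * nu * kx[keep] * ky[keep]
            det = gxx * gyy - gxy**2
            assert np.all(gxx > 0)
            assert np.all(det > 0)

    def test_invalid_poisson_ratio_rejected(self):
        with pytest.raises(ValueError, match="poisson"):
            fttm.GelSubstrate(poisson_ratio=0.6)
        with pytest.raises(ValueError, match="poisson"):
            fttm.GelSubstrate(poisson_ratio=0.0)


class TestForward:
    def test_zero_traction_zero_displacement(self, substrate48):
        zero = fttm.TractionField(np.zeros((48, 48)), np.zeros((48, 48)), 2.0)
        disp = fttm.forward_displacement(zero, substrate48)
        assert np.all(disp.u_x == 0) and np.all(disp.u_y == 0)

    def test_single_mode_closed_form(self):
        # T = (A cos(kx x), 0) with ky = 0 gives
        # u = (2(1+nu)(1-nu) A / (E kx)) cos(kx x) along x only
        n, spacing, E, nu = 64, 2.0, 1300.0, 0.48
        sub = fttm.GelSubstrate(E, nu, spacing, (n, n))
        gx, _ = piv.regular_grid((n, n), spacing)
        kx = 2 * np.pi * 3 / (n * spacing)
        A = 40.0
        T = fttm.TractionField(A * np.cos(kx * gx), np.zeros((n, n)), spacing)
        u = fttm.forward_displacement(T, sub, pad_factor=1)
        expected = 2 * (1 + nu) * (1 - nu) / (E * kx) * A * np.cos(kx * gx)
        np.testing.assert_allclose(u.u_x, expected, rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(u.u_y, 0.0, atol=1e-12)

    def test_agrees_with_real_space_oracle(self, substrate48, dipole_scene):
        dip, scene = dipole_scene
        oracle = synthgen.forward_displacement_oracle(scene, substrate48)
        fwd = fttm.forward_displacement(scene, substrate48, pad_factor=4)
        gx, gy = scene.coords()
        centers = [(47.0 - 10.0, 47.0), (47.0 + 10.0, 47.0)]
        away = np.ones(scene.shape, dtype=bool)
        for cx, cy in centers:
            away &= np.hypot(gx - cx, gy - cy) > 3 * dip.patch_sigma
        num = np.sqrt(((fwd.u_x - oracle.u_x) ** 2 + (fwd.u_y - oracle.u_y) ** 2)[away].mean())
        den = np.sqrt((oracle.u_x**2 + oracle.u_y**2)[away].mean())
        assert num / den < 0.02


class TestInvertUnconstrained:
    def test_round_trip_identity(self):
        sub = fttm.GelSubstrate(grid_spacing=2.0, grid_shape=(64, 64))
        T = random_periodic_traction((64, 64), 2.0, seed=1)
        u = fttm.forward_displacement(T, sub, pad_factor=1)
        T2 = fttm.invert_unconstrained(u, sub, pad_factor=1)
        err = np.sqrt(((T2.t_x - T.t_x) ** 2 + (T2.t_y - T.t_y) ** 2).mean())
        scale = np.sqrt((T.t_x**2 + T.t_y**2).mean())
        assert err / scale < 1e-6

    def test_zero_displacement_zero_traction(self, substrate48):
        gx, gy = piv.regular_grid((48, 48), 2.0)
        z = np.zeros((48, 48))
        u = piv.DisplacementField(gx, gy, z, z.copy(), np.ones((48, 48), bool))
        T = fttm.invert_unconstrained(u, substrate48)
        assert np.all(T.t_x == 0) and np.all(T.t_y == 0)

    def test_linearity_in_displacement(self, substrate48, dipole_scene):
        _, scene = dipole_scene
        u = fttm.forward_displacement(scene, substrate48)
        u2 = piv.DisplacementField(
            u.grid_x, u.grid_y, 2 * u.u_x, 2 * u.u_y, u.valid, u.pixel_size
        )
        Ta = fttm.invert_unconstrained(u, substrate48)
        Tb = fttm.invert_unconstrained(u2, substrate48)
        np.testing.assert_allclose(Tb.t_x, 2 * Ta.t_x, rtol=1e-10, atol=1e-9)


class TestInvertConstrained:
    def _scene_setup(self, substrate48, dipole_scene):
        dip, scene = dipole_scene
        u = fttm.forward_displacement(scene, substrate48, pad_factor=2)
        gx, gy = scene.coords()
        mask = np.hypot(gx - 47.0, gy - 47.0) <= 31.0
        return scene, u, fttm.CellMask(mask, scene.pixel_area)

    def test_recovers_masked_truth(self, substrate48, dipole_scene):
        scene, u, mask = self._scene_setup(substrate48, dipole_scene)
        rec = fttm.invert_constrained(u, substrate48, mask, pad_factor=2)
        err = np.sqrt(((rec.t_x - scene.t_x) ** 2 + (rec.t_y - scene.t_y) ** 2).mean())
        scale = np.sqrt((scene.t_x**2 + scene.t_y**2).mean())
        assert err / scale < 0.05
        assert np.all(rec.t_x[~mask.mask] == 0)
        assert np.all(rec.t_y[~mask.mask] == 0)

    def test_full_mask_equals_unconstrained(self):
        sub = fttm.GelSubstrate(grid_spacing=2.0, grid_shape=(32, 32))
        gx, gy = piv.regular_grid((32, 32), 2.0)
        kx = 2 * np.pi * 2 / 64
        tx = 30 * np.cos(kx * gx)
        ty = 15 * np.sin(kx * gy)
        T = fttm.TractionField(tx - tx.mean(), ty - ty.mean(), 2.0)
        u = fttm.forward_displacement(T, sub, pad_factor=1)
        unc = fttm.invert_unconstrained(u, sub, pad_factor=1)
        full = fttm.CellMask(np.ones((32, 32), bool), 4.0)
        con = fttm.invert_constrained(u, sub, full, pad_factor=1)
        np.testing.assert_allclose(con.t_x, unc.t_x, atol=1e-8)
        np.testing.assert_allclose(con.t_y, unc.t_y, atol=1e-8)

    def test_noise_stays_out_of_background(self, substrate48, dipole_scene):
        scene, u, mask = self._scene_setup(substrate48, dipole_scene)
        rng = np.random.default_rng(3)
        scale = 0.05 * np.abs(u.u_x).max()
        noisy = piv.DisplacementField(
            u.grid_x, u.grid_y,
            u.u_x + rng.normal(0, scale, u.shape),
            u.u_y + rng.normal(0, scale, u.shape),
            u.valid, u.pixel_size,
        )
        con = fttm.invert_constrained(noisy, substrate48, mask)
        unc = fttm.invert_unconstrained(noisy, substrate48)
        bg = ~mask.mask
        assert np.sqrt((con.t_x[bg] ** 2 + con.t_y[bg] ** 2).mean()) == 0.0
        assert np.sqrt((unc.t_x[bg] ** 2 + unc.t_y[bg] ** 2).mean()) > 0.0

    def test_constrained_residual_beats_masked_unconstrained(self, substrate48, dipole_scene):
        scene, u, mask = self._scene_setup(substrate48, dipole_scene)
        rng = np.random.default_rng(4)
        scale = 0.05 * np.abs(u.u_x).max()
        noisy = piv.DisplacementField(
            u.grid_x, u.grid_y,
            u.u_x + rng.normal(0, scale, u.shape),
            u.u_y + rng.normal(0, scale, u.shape),
            u.valid, u.pixel_size,
        )

        def residual(T):
            f = fttm.forward_displacement(T, substrate48, pad_factor=2)
            return np.sqrt(((f.u_x - noisy.u_x) ** 2 + (f.u_y - noisy.u_y) ** 2).sum())

        con = fttm.invert_constrained(noisy, substrate48, mask)
        unc = fttm.invert_unconstrained(noisy, substrate48)
        masked_unc = fttm.TractionField(
            np.where(mask.mask, unc.t_x, 0.0), np.where(mask.mask, unc.t_y, 0.0), unc.spacing
        )
        assert residual(con) <= residual(masked_unc) + 1e-9


class TestMechanicsMetrics:
    def test_uniform_traction_rms(self):
        shape = (8, 8)
        T = fttm.TractionField(np.full(shape, 30.0), np.full(shape, 40.0), 1.0)
        gx, gy = piv.regular_grid(shape, 1.0)
        u = piv.DisplacementField(gx, gy, np.zeros(shape), np.zeros(shape), np.ones(shape, bool))
        mask = fttm.CellMask(np.ones(shape, bool), 1.0)
        met = fttm.mechanics_metrics(T, u, mask)
        assert met.rms_traction == pytest.approx(50.0)

    def test_strain_energy_direct_quadrature(self):
        # 2x2 grid, uniform T = (100, 0) Pa, u = (0.1, 0) µm:
        # U = 0.5 * 100 * 0.1 * 4 px * 1 µm² = 20 Pa µm³ = 2e-5 pJ
        shape = (2, 2)
        T = fttm.TractionField(np.full(shape, 100.0), np.zeros(shape), 1.0)
        gx, gy = piv.regular_grid(shape, 1.0)
        u = piv.DisplacementField(gx, gy, np.full(shape, 0.1), np.zeros(shape), np.ones(shape, bool))
        mask = fttm.CellMask(np.ones(shape, bool), 1.0)
        met = fttm.mechanics_metrics(T, u, mask)
        assert met.strain_energy == pytest.approx(2e-5, rel=1e-12)

    def test_strain_energy_nonnegative_for_consistent_pairs(self, substrate48):
        for seed in range(3):
            T = random_periodic_traction((48, 48), 2.0, seed=seed)
            u = fttm.forward_displacement(T, substrate48, pad_factor=1)
            mask = fttm.CellMask(np.ones((48, 48), bool), 4.0)
            met = fttm.mechanics_metrics(T, u, mask)
            assert met.strain_energy >= 0

    def test_moment_invariant_under_grid_translation(self, substrate48, dipole_scene):
        # shifting a force-balanced field across the grid must not change
        # the centroid-referenced contractile moment
        _, scene = dipole_scene
        gx, gy = piv.regular_grid(scene.shape, scene.spacing)
        z = np.zeros(scene.shape)
        u = piv.DisplacementField(gx, gy, z, z.copy(), np.ones(scene.shape, bool))
        mask = fttm.CellMask(np.ones(scene.shape, bool), scene.pixel_area)
        met0 = fttm.mechanics_metrics(scene, u, mask)
        shifted = fttm.TractionField(
            np.roll(scene.t_x, (3, -4), (0, 1)), np.roll(scene.t_y, (3, -4), (0, 1)), scene.spacing
        )
        met1 = fttm.mechanics_metrics(shifted, u, mask)
        assert met1.net_contractile_moment == pytest.approx(
            met0.net_contractile_moment, rel=1e-9
        )

    def test_dipole_moment_value_and_sign(self, substrate48, dipole_scene):
        _, scene = dipole_scene
        gx, gy = piv.regular_grid(scene.shape, scene.spacing)
        z = np.zeros(scene.shape)
        u = piv.DisplacementField(gx, gy, z, z.copy(), np.ones(scene.shape, bool))
        mask = fttm.CellMask(np.ones(scene.shape, bool), scene.pixel_area)
        met = fttm.mechanics_metrics(scene, u, mask)
        assert met.net_contractile_moment == pytest.approx(2.0, rel=1e-6)
        assert met.net_contractile_moment_signed == pytest.approx(-2.0, rel=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fttm.CellMask(np.zeros((4, 4), bool), 1.0)
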