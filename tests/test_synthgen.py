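"""Generators: force balance, Boussinesq oracle, fBm statistics, scenes."""

import numpy as np
import pandas as pd
import pytest

from cytomech import fttm, piv, sntm, synthgen


class TestTractionScene:
    def test_zero_dipoles_gives_zero_field(self, substrate48):
        scene = synthgen.make_traction_scene(substrate48, [])
        assert np.all(scene.t_x == 0) and np.all(scene.t_y == 0)

    def test_force_balance(self, substrate48, dipole_scene):
        _, scene = dipole_scene
        net = np.hypot(*scene.net_force())
        total = scene.magnitude().sum() * scene.pixel_area
        assert net < 1e-6 * total

    def test_two_identical_dipoles_doubles_field(self, substrate48):
        dip = synthgen.DipoleSpec(center=(47.0, 47.0))
        one = synthgen.make_traction_scene(substrate48, [dip])
        two = synthgen.make_traction_scene(substrate48, [dip, dip])
        np.testing.assert_allclose(two.t_x, 2 * one.t_x, rtol=1e-12)
        np.testing.assert_allclose(two.t_y, 2 * one.t_y, rtol=1e-12)

    def test_contractile_dipole_moment_is_force_times_separation(self, substrate48, dipole_scene):
        # |mu| = F*d = 1e5 pN * 20 µm = 2 pNm, negative trace for contraction
        _, scene = dipole_scene
        mask = fttm.CellMask(np.ones(scene.shape, dtype=bool), scene.pixel_area)
        zero_u = piv.DisplacementField(
            *piv.regular_grid(scene.shape, scene.spacing),
            np.zeros(scene.shape), np.zeros(scene.shape),
            np.ones(scene.shape, dtype=bool),
        )
        met = fttm.mechanics_metrics(scene, zero_u, mask)
        assert met.net_contractile_moment == pytest.approx(2.0, rel=1e-6)
        assert met.net_contractile_moment_signed < 0

    def test_patch_off_grid_rejected(self, substrate48):
        dip = synthgen.DipoleSpec(center=(2.0, 47.0))
        with pytest.raises(ValueError, match="off the grid|boundary"):
            synthgen.make_traction_scene(substrate48, [dip])

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError, match="unit vector"):
            synthgen.DipoleSpec(center=(47.0, 47.0), axis=(1.0, 1.0))


class TestDisplacementOracle:
    def test_zero_traction_zero_displacement(self, substrate48):
        scene = synthgen.make_traction_scene(substrate48, [])
        disp = synthgen.forward_displacement_oracle(scene, substrate48)
        assert np.all(disp.u_x == 0) and np.all(disp.u_y == 0)

    def test_point_force_displacement_north_of_source(self):
        # along the perpendicular, r_x = 0 kills the r_i r_j term:
        # u_x = (1+nu)(1-nu) F_x / (pi E r), u_y = 0
        sub = fttm.GelSubstrate(grid_spacing=1.0, grid_shape=(33, 33))
        tx = np.zeros((33, 33))
        tx[16, 16] = 100.0  # Pa on a 1 µm² pixel -> 100 pN
        scene = fttm.TractionField(tx, np.zeros_like(tx), 1.0)
        disp = synthgen.forward_displacement_oracle(scene, sub)
        r = 10.0
        expected = (1 + 0.48) * (1 - 0.48) * 100.0 / (np.pi * 1300.0 * r)
        assert disp.u_x[26, 16] == pytest.approx(expected, rel=1e-12)
        assert disp.u_y[26, 16] == pytest.approx(0.0, abs=1e-15)

    def test_doubling_modulus_halves_displacement(self, substrate48, dipole_scene):
        _, scene = dipole_scene
        stiff = fttm.GelSubstrate(
            youngs_modulus=2600.0, poisson_ratio=0.48, grid_spacing=2.0, grid_shape=(48, 48)
        )
        soft_disp = synthgen.forward_displacement_oracle(scene, substrate48)
        stiff_disp = synthgen.forward_displacement_oracle(scene, stiff)
        np.testing.assert_allclose(stiff_disp.u_x, soft_disp.u_x / 2, rtol=1e-12)

    def test_linearity(self, substrate48):
        rng = np.random.default_rng(0)
        t1 = fttm.TractionField(rng.normal(size=(48, 48)), rng.normal(size=(48, 48)), 2.0)
        t2 = fttm.TractionField(rng.normal(size=(48, 48)), rng.normal(size=(48, 48)), 2.0)
        combo = fttm.TractionField(2.0 * t1.t_x - 3.0 * t2.t_x, 2.0 * t1.t_y - 3.0 * t2.t_y, 2.0)
        u1 = synthgen.forward_displacement_oracle(t1, substrate48)
        u2 = synthgen.forward_displacement_oracle(t2, substrate48)
        uc = synthgen.forward_displacement_oracle(combo, substrate48)
        np.testing.assert_allclose(uc.u_x, 2 * u1.u_x - 3 * u2.u_x, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(uc.u_y, 2 * u1.u_y - 3 * u2.u_y, rtol=1e-10, atol=1e-12)


class TestBeadImages:
    def _zero_field(self, shape=(64, 64)):
        gx, gy = piv.regular_grid(shape, 1.0)
        z = np.zeros(shape)
        return piv.DisplacementField(gx, gy, z, z.copy(), np.ones(shape, bool))

    def test_zero_displacement_identical_pair(self):
        pair = synthgen.render_bead_images(self._zero_field(), n_beads=30, noise_sd=0.0, seed=1)
        np.testing.assert_array_equal(pair.reference, pair.deformed)

    def test_uniform_shift_translates_reference(self):
        shape = (64, 64)
        gx, gy = piv.regular_grid(shape, 1.0)
        disp = piv.DisplacementField(
            gx, gy, np.full(shape, 3.0), np.zeros(shape), np.ones(shape, bool)
        )
        pair = synthgen.render_bead_images(disp, n_beads=10, noise_sd=0.0, seed=2)
        # analytic re-rendering at shifted centers == translation of the
        # reference wherever spot support stays inside the frame
        interior = pair.reference[:, : 64 - 10]
        np.testing.assert_allclose(pair.deformed[:, 3 : 64 - 7], interior, atol=1e-6)

    def test_seed_reproducibility(self):
        f = self._zero_field()
        a = synthgen.render_bead_images(f, 20, noise_sd=0.05, seed=7)
        b = synthgen.render_bead_images(f, 20, noise_sd=0.05, seed=7)
        np.testing.assert_array_equal(a.reference, b.reference)
        np.testing.assert_array_equal(a.deformed, b.deformed)

    def test_zero_beads_rejected(self):
        with pytest.raises(ValueError, match="n_beads"):
            synthgen.render_bead_images(self._zero_field(), n_beads=0)


class TestTrajectories:
    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            synthgen.ActiveTrajectoryModel(alpha_true=2.0)
        with pytest.raises(ValueError):
            synthgen.ActiveTrajectoryModel(alpha_true=0.0)

    def test_brownian_increments_uncorrelated(self):
        model = synthgen.ActiveTrajectoryModel(
            alpha_true=1.0, dstar_true=4.0, n_beads=100, duration=100.0, seed=3
        )
        traj = synthgen.simulate_trajectories(model)
        rhos = []
        for _, _, xy in traj.iter_tracks():
            inc = np.diff(xy[:, 0])
            rhos.append(np.corrcoef(inc[:-1], inc[1:])[0, 1])
        n_inc = 99 * 100
        assert abs(np.mean(rhos)) < 3 / np.sqrt(n_inc)

    def test_ensemble_msd_matches_closed_form(self):
        # MSD(16 s) = 2 * 16**1.5 = 128 nm² within 10%
        model = synthgen.ActiveTrajectoryModel(
            alpha_true=1.5, dstar_true=2.0, n_beads=200, duration=300.0, seed=11
        )
        traj = synthgen.simulate_trajectories(model)
        curve = sntm.compute_msd(traj, max_lag_s=32.0)
        msd16 = curve.msd_nm2[curve.lag_s == 16.0][0]
        assert msd16 == pytest.approx(128.0, rel=0.10)

    def test_msd_within_3_se_at_dyadic_lags(self):
        model = synthgen.ActiveTrajectoryModel(
            alpha_true=1.4, dstar_true=3.0, n_beads=500, duration=64.0, seed=5
        )
        traj = synthgen.simulate_trajectories(model)
        curve = sntm.compute_msd(traj, max_lag_s=32.0, averaging="ensemble_only")
        for lag in (1.0, 2.0, 4.0, 8.0, 16.0, 32.0):
            target = 3.0 * lag**1.4
            observed = curve.msd_nm2[curve.lag_s == lag][0]
            # X = dx² + dy² with Gaussian components: Var X = (E X)², so
            # the SE of the 500-bead mean is target / sqrt(500)
            se = target / np.sqrt(500)
            assert abs(observed - target) < 3 * se, f"lag {lag}"

    def test_seed_reproducibility(self):
        m = synthgen.ActiveTrajectoryModel(seed=9)
        a = synthgen.simulate_trajectories(m).frames
        b = synthgen.simulate_trajectories(m).frames
        pd.testing.assert_frame_equal(a, b)


class TestColocScene:
    def test_full_overlap_no_extras_identical_channels(self):
        scene = synthgen.ColocScene(overlap_fraction=1.0, n_extra_b=0, noise_sd=0.0, seed=1)
        pair, truth = synthgen.make_coloc_scene(scene)
        np.testing.assert_allclose(pair.channel_a, pair.channel_b, atol=1e-12)
        assert truth["overlap_fraction_true"] == 1.0

    def test_zero_overlap_no_shared_centers(self):
        scene = synthgen.ColocScene(overlap_fraction=0.0, seed=2)
        _, truth = synthgen.make_coloc_scene(scene)
        a = {tuple(p) for p in truth["positions_a"]}
        b = {tuple(p) for p in truth["positions_b"]}
        assert not a & b


class TestCtTable:
    def test_noise_free_single_equivalent_hits_intercept(self):
        spec = synthgen.QpcrSimSpec(
            efficiency=1.0, intercept_ct=38.0, noise_sd=0.0, true_equivalents=(1.0,)
        )
        tab = synthgen.simulate_ct_table(spec)
        sample_ct = tab.loc[~tab["is_standard"], "ct"]
        assert np.allclose(sample_ct, 38.0)

    @pytest.mark.parametrize(
        "efficiency, expected_delta",
        [(1.0, -1.0 / np.log10(2.0)), (0.9, -1.0 / np.log10(1.9))],
    )
    def test_tenfold_dilution_delta_ct(self, efficiency, expected_delta):
        spec = synthgen.QpcrSimSpec(
            efficiency=efficiency, noise_sd=0.0, true_equivalents=(1.0, 10.0)
        )
        tab = synthgen.simulate_ct_table(spec)
        unk = tab[~tab["is_standard"]].groupby("sample")["ct"].mean()
        assert unk["sample_1"] - unk["sample_0"] == pytest.approx(expected_delta, abs=1e-9)

    def test_nonpositive_equivalents_rejected(self):
        with pytest.raises(ValueError):
            synthgen.QpcrSimSpec(true_equivalents=(10.0, 0.0))
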