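"""Rotation extraction, rocking correlation functions and their fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from rockdyn.rocking import (CorrelationFunction, DegenerateFitError,
                             aggregate_and_flag, fit_biexp_base, fit_rotation,
                             log_lag_grid, rocking_correlation,
                             rotation_series, sphere_vectors, RotationSeries)
from rockdyn.synthetic import (RockingProcess, assemble_trajectory,
                               rigid_body_plateau, simulate_rocking_series)


def _p2(x):
    return 1.5 * x * x - 0.5


class TestFitRotation:
    def test_identity_on_equal_sets(self, template):
        xyz, _ = template
        R, rmsd = fit_rotation(xyz, xyz)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_rotation(self, template):
        xyz, _ = template
        R_true = Rotation.from_rotvec(np.deg2rad(5.0) * np.array([0, 0, 1.0]))
        mobile = R_true.apply(xyz - xyz.mean(0)) + xyz.mean(0) + [3.0, -1.0, 2.0]
        R, rmsd = fit_rotation(mobile, xyz)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        err = Rotation.from_matrix(R.T @ R_true.as_matrix()).magnitude()
        assert err < 1e-10

    def test_noisy_fit_beats_angle_grid_oracle(self, template):
        """With coordinate noise, no rotation on a fine angle grid about
        the fitted axis achieves a lower RMSD than the least-squares fit."""
        xyz, _ = template
        rng = np.random.default_rng(21)
        R_true = Rotation.from_rotvec(np.deg2rad(5.0) * np.array([0.3, 0.9, 0.1])
                                      / np.linalg.norm([0.3, 0.9, 0.1]))
        mobile = R_true.apply(xyz - xyz.mean(0)) + xyz.mean(0) \
            + rng.normal(0, 0.1, xyz.shape)
        R, rmsd = fit_rotation(mobile, xyz)
        rot = Rotation.from_matrix(R)
        axis = rot.as_rotvec() / rot.magnitude()
        ref_c = xyz - xyz.mean(0)
        mob_c = mobile - mobile.mean(0)

        def rmsd_of(rot_try):
            return np.sqrt(np.mean(np.sum(
                (rot_try.apply(ref_c) - mob_c) ** 2, axis=1)))

        angles = rot.magnitude() + np.deg2rad(np.arange(-50, 51) * 0.01)
        grid_rmsds = [rmsd_of(Rotation.from_rotvec(a * axis)) for a in angles]
        assert rmsd <= min(grid_rmsds) + 1e-12
        # fitted angle within one grid step of the grid optimum
        assert abs(angles[int(np.argmin(grid_rmsds))] - rot.magnitude()) \
            <= np.deg2rad(0.011)

    def test_degenerate_selections_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateFitError):
            fit_rotation(line, line)
        with pytest.raises(DegenerateFitError):
            fit_rotation(line[:2], line[:2])

    def test_reflection_case_forced_proper(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(12, 3))
        mobile = ref.copy()
        mobile[:, 0] *= -1  # mirrored target
        R, _ = fit_rotation(mobile, ref)
        assert np.linalg.det(R) == pytest.approx(1.0)


class TestRotationSeries:
    def test_static_trajectory_gives_identity(self, small_lattice):
        traj = assemble_trajectory(small_lattice, None, None, 5, 1e-9)
        for s in rotation_series(traj, small_lattice):
            np.testing.assert_allclose(s.matrices,
                                       np.broadcast_to(np.eye(3), (5, 3, 3)),
                                       atol=1e-10)
            assert s.fit_rmsd.max() < 1e-10

    def test_recovers_input_rocking_rotations(self, small_lattice):
        proc = RockingProcess("restrained_diffusion", angular_stddev=0.05,
                              relaxation_time=1e-8, seed=42)
        traj = assemble_trajectory(small_lattice, proc, None, 200, 1e-9)
        series = rotation_series(traj, small_lattice)
        seeds = np.random.SeedSequence(42).spawn(small_lattice.n_molecules)
        for mi, s in enumerate(series):
            mats_in = simulate_rocking_series(
                proc, 200, 1e-9, rng=np.random.default_rng(seeds[mi]))
            # measured rotations are the lab-frame input conjugated by the
            # molecule's lattice rotation
            T = small_lattice.transforms[mi].rotation
            expected = np.einsum("ba,fbc,cd->fad", T, mats_in, T)
            err = Rotation.from_matrix(
                np.einsum("fab,fcb->fac", s.matrices, expected)).magnitude()
            assert err.max() < 1e-6

    def test_internal_motion_does_not_leak_into_rotations(self, small_lattice):
        from rockdyn.synthetic import InternalMotion
        internal = InternalMotion(cone_semiangle=20.0, correlation_time=1e-10,
                                  seed=9)
        traj = assemble_trajectory(small_lattice, None, internal, 50, 1e-9)
        for s in rotation_series(traj, small_lattice):
            # CA selection excludes H; bound set by arccos precision at
            # trace ~ 3, not by any genuine rotation
            assert s.max_angle() < 1e-6

    def test_nonfinite_coordinates_reported(self, small_lattice):
        traj = assemble_trajectory(small_lattice, None, None, 5, 1e-9)
        traj.coordinates[3, 1, 0, 0] = np.nan
        with pytest.raises(ValueError, match="molecule 1, frame 3"):
            rotation_series(traj, small_lattice)


class TestSphereVectors:
    def test_conventions_and_uniformity(self):
        np.testing.assert_array_equal(sphere_vectors(1), [[0.0, 0.0, 1.0]])
        u = sphere_vectors(100)
        np.testing.assert_allclose(np.linalg.norm(u, axis=1), 1.0, atol=1e-12)
        eigs = np.linalg.eigvalsh(u.T @ u / 100)
        assert np.abs(eigs - 1.0 / 3.0).max() < 0.01

    def test_pair_p2_isotropy_vs_montecarlo(self):
        """Mean P2 over all vector pairs ~ 0, as for ideal isotropy
        (Monte-Carlo reference value |mean| < 1e-3 at 10^6 draws)."""
        u = sphere_vectors(100)
        dots = u @ u.T
        iu = np.triu_indices(100, 1)
        assert abs(_p2(dots[iu]).mean()) < 0.02

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            sphere_vectors(0)


class TestRockingCorrelation:
    def test_identity_series_gives_unity(self):
        mats = np.broadcast_to(np.eye(3), (50, 3, 3)).copy()
        s = RotationSeries(mats, "A", np.zeros(50), 1e-9)
        c = rocking_correlation(s, sphere_vectors(20), np.array([0, 1, 5, 10]))
        np.testing.assert_allclose(c.values, 1.0, atol=1e-12)
        assert c.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_nested_loop_oracle(self):
        """Fourth-moment contraction equals the explicit double sum over
        origins and vectors on a small series."""
        rng = np.random.default_rng(17)
        mats = Rotation.from_rotvec(rng.normal(0, 0.3, (10, 3))).as_matrix()
        s = RotationSeries(mats, "A", np.zeros(10), 1e-9)
        vecs = sphere_vectors(7)
        lags = np.array([0, 1, 3, 7])
        c = rocking_correlation(s, vecs, lags)
        for li, L in enumerate(lags):
            acc = []
            for t in range(10 - L):
                for u in vecs:
                    acc.append(_p2(np.dot(mats[t] @ u, mats[t + L] @ u)))
            assert c.values[li] == pytest.approx(np.mean(acc), abs=1e-12)

    def test_two_site_jump_plateau(self):
        """g_rock of a rigid-body 90-degree jump decays to the rigid-body
        closed form (2 + 2cos^2 Phi + cos Phi)/5 = 0.4."""
        proc = RockingProcess("two_site_jump", jump_angle_phi=90.0,
                              exchange_rate=5e7, seed=13)
        mats = simulate_rocking_series(proc, 100_000, 1e-9)
        s = RotationSeries(mats, "A", np.zeros(100_000), 1e-9)
        c = rocking_correlation(s, sphere_vectors(100),
                                np.array([0, 500, 750, 1000]))
        assert np.mean(c.values[1:]) == pytest.approx(
            rigid_body_plateau(90.0), abs=0.02)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_global_rotation(self, seed):
        """g_rock is unchanged when every Xi(t) is pre-multiplied by one
        global rotation (isotropy of the vector set)."""
        rng = np.random.default_rng(seed)
        mats = Rotation.from_rotvec(rng.normal(0, 0.1, (40, 3))).as_matrix()
        G = Rotation.from_rotvec(rng.normal(0, 1.5, 3)).as_matrix()
        vecs = sphere_vectors(100)
        lags = np.array([0, 1, 5, 20])
        c1 = rocking_correlation(
            RotationSeries(mats, "A", np.zeros(40), 1e-9), vecs, lags)
        c2 = rocking_correlation(
            RotationSeries(G[None] @ mats, "A", np.zeros(40), 1e-9), vecs, lags)
        np.testing.assert_allclose(c1.values, c2.values, atol=0.005)

    def test_empty_lag_grid_rejected(self):
        mats = np.broadcast_to(np.eye(3), (10, 3, 3)).copy()
        s = RotationSeries(mats, "A", np.zeros(10), 1e-9)
        with pytest.raises(ValueError):
            rocking_correlation(s, sphere_vectors(5), np.array([], dtype=int))


class TestAggregation:
    def _curve(self, values, label="x"):
        lags = np.arange(len(values), dtype=float) * 1e-9
        return CorrelationFunction(lags, np.asarray(values, dtype=float),
                                   np.ones(len(values), dtype=int), label=label)

    def test_identical_curves_no_outliers(self):
        curves = [self._curve([1, 0.9, 0.8, 0.75]) for _ in range(5)]
        mean, flags = aggregate_and_flag(curves)
        assert not flags.any()
        np.testing.assert_allclose(mean.values, curves[0].values)

    def test_single_divergent_curve_flagged(self):
        curves = [self._curve([1, 0.9, 0.8, 0.75]) for _ in range(9)]
        curves.append(self._curve([1, 0.3, 0.05, 0.0], label="bad"))
        mean, flags = aggregate_and_flag(curves)
        assert flags.sum() == 1 and flags[-1]
        np.testing.assert_allclose(mean.values, [1, 0.9, 0.8, 0.75])

    def test_mean_of_homogeneous_ensemble_matches_long_run(self):
        """24 short-trajectory curves average to the long-run expectation
        of the shared process."""
        lags = np.array([0, 50, 200, 800])
        vecs = sphere_vectors(50)
        proc = RockingProcess("restrained_diffusion", angular_stddev=0.1,
                              relaxation_time=2e-8, seed=0)
        curves = []
        rngs = np.random.SeedSequence(77).spawn(24)
        for i in range(24):
            mats = simulate_rocking_series(proc, 4000, 1e-9,
                                           rng=np.random.default_rng(rngs[i]))
            curves.append(rocking_correlation(
                RotationSeries(mats, str(i), np.zeros(4000), 1e-9), vecs, lags))
        mean, flags = aggregate_and_flag(curves)
        long_mats = simulate_rocking_series(
            proc, 40_000, 1e-9, rng=np.random.default_rng(123456))
        ref = rocking_correlation(
            RotationSeries(long_mats, "ref", np.zeros(40_000), 1e-9), vecs, lags)
        np.testing.assert_allclose(mean.values, ref.values, atol=0.01)

    def test_inconsistent_grids_rejected(self):
        a = self._curve([1, 0.9, 0.8, 0.7])
        b = CorrelationFunction(np.array([0, 2e-9, 4e-9]), np.array([1, 0.9, 0.8]),
                                np.ones(3, dtype=int))
        with pytest.raises(ValueError):
            aggregate_and_flag([a, b])


class TestBiExpFit:
    def _grid(self):
        return log_lag_grid(1e-9, 1e-4) * 1e-9

    def test_flat_curve(self):
        tau = self._grid()
        c = CorrelationFunction(tau, np.ones_like(tau),
                                np.ones_like(tau, dtype=int))
        fit = fit_biexp_base(c)
        assert fit.plateau == pytest.approx(1.0, abs=1e-6)
        assert fit.c_f + fit.c_s == pytest.approx(0.0, abs=1e-6)

    def test_recovers_well_separated_components(self):
        """tau_s/tau_f = 300: parameters identifiable to 1% noise-free."""
        tau = self._grid()
        y = 0.955 + 0.005 * np.exp(-tau / 1e-9) + 0.04 * np.exp(-tau / 3e-7)
        fit = fit_biexp_base(CorrelationFunction(
            tau, y, np.ones_like(tau, dtype=int)))
        assert fit.c_f == pytest.approx(0.005, rel=0.01)
        assert fit.tau_f == pytest.approx(1e-9, rel=0.01)
        assert fit.c_s == pytest.approx(0.04, rel=0.01)
        assert fit.tau_s == pytest.approx(3e-7, rel=0.01)
        assert fit.plateau == pytest.approx(0.955, abs=1e-4)
        assert fit.tau_f <= fit.tau_s

    def test_slow_component_merges_degenerate_split(self):
        """A mono-exponential decay fit by two exponentials reads out as a
        single slow component with the correct amplitude-weighted tau."""
        tau = self._grid()
        y = 0.957 + 0.043 * np.exp(-tau / 5e-7)
        fit = fit_biexp_base(CorrelationFunction(
            tau, y, np.ones_like(tau, dtype=int)))
        c_s, tau_s = fit.slow_component()
        assert c_s == pytest.approx(0.043, rel=0.02)
        assert tau_s == pytest.approx(5e-7, rel=0.05)

    def test_too_few_points_rejected(self):
        c = CorrelationFunction(np.array([0, 1e-9, 2e-9]),
                                np.ones(3), np.ones(3, dtype=int))
        with pytest.raises(ValueError):
            fit_biexp_base(c)
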