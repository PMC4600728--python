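"""Internal dynamics: superposition, order parameters, NH correlation
functions, multi-exponential fits, spectral densities and 15N R1."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rockdyn.conditions import SpectrometerConditions
from rockdyn.internal import (fit_multiexp, global_s2_scaling,
                              nh_vector_series, r1_nitrogen,
                              s2_bruschweiler_wright, symmetry_superpose,
                              vector_correlation)
from rockdyn.modelfree import ModelFreeMotion, spectral_density
from rockdyn.rocking import (CorrelationFunction, log_lag_grid,
                             rocking_correlation, rotation_series,
                             sphere_vectors)
from rockdyn.synthetic import RockingProcess, assemble_trajectory


def _p2(x):
    return 1.5 * x * x - 0.5


class TestSuperposition:
    def test_identity_transforms_are_noop(self, template):
        from rockdyn.lattice import LatticeSpec, SymmetryOp, build_reference_lattice
        from conftest import ORTHO_CELL
        xyz, atoms = template
        lat = build_reference_lattice(
            LatticeSpec(ORTHO_CELL, [SymmetryOp.identity()], xyz, atoms))
        traj = assemble_trajectory(lat, None, None, 4, 1e-9)
        out = symmetry_superpose(traj, lat)
        np.testing.assert_allclose(out.coordinates, traj.coordinates,
                                   atol=1e-12)

    def test_all_molecules_map_onto_template(self, small_lattice, template):
        xyz, _ = template
        traj = assemble_trajectory(small_lattice, None, None, 3, 1e-9)
        out = symmetry_superpose(traj, small_lattice)
        for mi in range(out.n_molecules):
            np.testing.assert_allclose(out.coordinates[0, mi], xyz, atol=1e-8)

    def test_concatenated_series_length(self, small_lattice):
        traj = assemble_trajectory(small_lattice, None, None, 1000, 1e-9)
        vs = nh_vector_series(traj, small_lattice)
        assert vs.concatenated().shape[0] == 4 * 1000

    def test_roundtrip_through_transforms(self, small_lattice):
        traj = assemble_trajectory(small_lattice, None, None, 3, 1e-9)
        sup = symmetry_superpose(traj, small_lattice)
        for mi in range(traj.n_molecules):
            t = small_lattice.transforms[mi]
            back = sup.coordinates[:, mi] @ t.rotation.T + t.translation
            np.testing.assert_allclose(back, traj.coordinates[:, mi], atol=1e-8)


class TestOrderParameter:
    def test_static_vector_is_rigid(self):
        v = np.tile([0.0, 0.6, 0.8], (100, 1))
        assert s2_bruschweiler_wright(v) == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_limit_is_zero(self):
        rng = np.random.default_rng(31)
        v = rng.normal(size=(1_000_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert abs(s2_bruschweiler_wright(v)) < 0.003

    def test_cone_model_closed_form(self):
        """Uniform diffusion in a cone of semi-angle theta0:
        S2 = [cos(theta0) (1 + cos(theta0)) / 2]^2."""
        rng = np.random.default_rng(8)
        th0 = np.deg2rad(20.0)
        n = 400_000
        c = rng.uniform(np.cos(th0), 1.0, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        s = np.sqrt(1 - c ** 2)
        v = np.column_stack([s * np.cos(phi), s * np.sin(phi), c])
        closed = (np.cos(th0) * (1 + np.cos(th0)) / 2) ** 2
        assert s2_bruschweiler_wright(v) == pytest.approx(closed, abs=0.005)

    def test_bounds_and_input_validation(self):
        rng = np.random.default_rng(12)
        v = rng.normal(size=(500, 4, 3))
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        s2 = s2_bruschweiler_wright(v)
        assert np.all(s2 >= -1e-9) and np.all(s2 <= 1 + 1e-9)
        with pytest.raises(ValueError):
            s2_bruschweiler_wright(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            s2_bruschweiler_wright(np.ones((1, 3)))


class TestVectorCorrelation:
    def test_rigid_molecule_rigid_nh_gives_unity(self, small_lattice):
        traj = assemble_trajectory(small_lattice, None, None, 50, 1e-9)
        vs = nh_vector_series(traj, small_lattice)
        for c in vector_correlation(vs, np.array([0, 1, 10, 40])):
            np.testing.assert_allclose(c.values, 1.0, atol=1e-9)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(1, 10, 3, 3))
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        from rockdyn.internal import VectorSeries
        vs = VectorSeries(v, np.array([1, 2, 3]), 1e-9)
        lags = np.array([0, 1, 4])
        curves = vector_correlation(vs, lags)
        for r in range(3):
            for li, L in enumerate(lags):
                acc = [_p2(np.dot(v[0, t, r], v[0, t + L, r]))
                       for t in range(10 - L)]
                assert curves[r].values[li] == pytest.approx(np.mean(acc),
                                                             abs=1e-12)

    def test_rocking_only_equals_grock_for_every_residue(self, small_lattice):
        """Rigid-body equivalence: with internal motion off, every NH
        correlation function equals the isotropic rocking curve."""
        proc = RockingProcess("restrained_diffusion", angular_stddev=0.1,
                              relaxation_time=5e-9, seed=3)
        traj = assemble_trajectory(small_lattice, proc, None, 5000, 1e-9)
        lags = np.array([0, 2, 10, 50, 200, 1000])
        series = rotation_series(traj, small_lattice)
        g = np.mean([rocking_correlation(s, sphere_vectors(100), lags).values
                     for s in series], axis=0)
        vs = nh_vector_series(traj, small_lattice)
        for c in vector_correlation(vs, lags):
            np.testing.assert_allclose(c.values, g, atol=0.01)


class TestMultiExp:
    def _curve(self, y, tau):
        return CorrelationFunction(tau, y, np.ones_like(tau, dtype=int))

    def test_single_exponential_recovery(self):
        tau = log_lag_grid(1e-9, 1e-4) * 1e-9
        y = 0.9 + 0.1 * np.exp(-tau / 5e-8)
        fit = fit_multiexp(self._curve(y, tau))
        assert fit.constant == pytest.approx(0.9, abs=1e-4)
        amps = fit.amplitudes
        taus = fit.taus
        total = amps.sum()
        tau_eff = np.sum(amps * taus) / total
        assert total == pytest.approx(0.1, rel=0.02)
        assert tau_eff == pytest.approx(5e-8, rel=0.02)

    def test_constant_curve(self):
        tau = log_lag_grid(1e-9, 1e-4) * 1e-9
        fit = fit_multiexp(self._curve(np.full_like(tau, 0.9), tau))
        assert fit.constant == pytest.approx(0.9, abs=1e-6)
        assert fit.amplitudes.sum() == pytest.approx(0.0, abs=1e-6)

    def test_three_component_reconstruction(self):
        tau = log_lag_grid(1e-9, 1e-4) * 1e-9
        y = (0.85 + 0.05 * np.exp(-tau / 2e-9) + 0.06 * np.exp(-tau / 8e-8)
             + 0.04 * np.exp(-tau / 2e-6))
        fit = fit_multiexp(self._curve(y, tau))
        assert np.abs(fit.evaluate(tau) - y).max() < 1e-3

    def test_tau_cap_respected(self):
        tau = log_lag_grid(1e-9, 1e-5) * 1e-9
        y = 0.5 + 0.5 * np.exp(-tau / 1e-4)  # slower than the cap
        fit = fit_multiexp(self._curve(y, tau), tau_cap=1e-6)
        assert np.all(fit.taus <= 1e-6 * (1 + 1e-12))

    def test_all_zero_curve_rejected(self):
        tau = log_lag_grid(1e-9, 1e-5) * 1e-9
        from rockdyn.rocking import FitFailureError
        with pytest.raises(FitFailureError):
            fit_multiexp(self._curve(np.zeros_like(tau), tau))


class TestSpectralDensity:
    def test_single_component_closed_form(self):
        m = [(1.0, 3e-9)]
        assert spectral_density(m, np.array([0.0]))[0] == pytest.approx(
            0.4 * 3e-9)
        w = 1.0 / 3e-9
        assert spectral_density(m, np.array([w]))[0] == pytest.approx(
            0.4 * 3e-9 / 2.0)

    def test_monotone_decay_to_zero(self):
        m = ModelFreeMotion(0.8, [(0.15, 1e-9), (0.05, 1e-7)])
        w = np.logspace(5, 12, 40)
        J = spectral_density(m, w)
        assert np.all(np.diff(J) < 0)
        assert J[-1] < 1e-3 * J[0]

    def test_matches_cosine_transform_oracle(self):
        """J(w) = (2/5) int_0^inf C_mod(t) cos(wt) dt, numerically."""
        comps = [(0.06, 5e-9), (0.04, 2e-7)]
        w = np.logspace(6, 10, 9)
        J = spectral_density(comps, w)
        t = np.linspace(0, 1e-5, 2_000_001)
        ct = 0.06 * np.exp(-t / 5e-9) + 0.04 * np.exp(-t / 2e-7)
        J_num = np.array([0.4 * np.trapezoid(ct * np.cos(wi * t), t)
                          for wi in w])
        np.testing.assert_allclose(J_num, J, rtol=0.01)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            spectral_density([(0.1, -1e-9)], np.array([1e6]))


class TestR1:
    def test_rigid_limit_is_zero(self):
        cond = SpectrometerConditions()
        assert r1_nitrogen(ModelFreeMotion(1.0, []), cond) == 0.0

    def test_term_by_term_constant_oracle(self):
        """Independent evaluation of every term with explicit physical
        constants (CODATA), for one-component motion at 600 MHz."""
        cond = SpectrometerConditions(proton_larmor=600e6, r_nh=1.02,
                                      delta_sigma_n=-170.0)
        s2, tau = 0.9, 5e-9
        got = r1_nitrogen(ModelFreeMotion.single(s2, tau), cond)

        mu0, hbar = 1.25663706212e-6, 1.054571817e-34
        gh, gn = 2.6752218744e8, 2.7126e7
        d = mu0 / (4 * np.pi) * gh * gn * hbar / (1.02e-10) ** 3
        wh = 2 * np.pi * 600e6
        wn = wh * gn / gh
        c2 = (170e-6 * wn) ** 2 / 3

        def J(w):
            return 0.4 * (1 - s2) * tau / (1 + (w * tau) ** 2)

        expected = (d ** 2 / 4 * (J(wh - wn) + 3 * J(wn) + 6 * J(wh + wn))
                    + c2 * J(wn))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_single_maximum_near_omega_n(self):
        cond = SpectrometerConditions()
        taus = np.logspace(-11, -6, 120)
        r1 = np.array([r1_nitrogen(ModelFreeMotion.single(0.9, t), cond)
                       for t in taus])
        k = int(np.argmax(r1))
        assert 0 < k < len(taus) - 1
        assert np.all(np.diff(r1[:k + 1]) > 0) and np.all(np.diff(r1[k:]) < 0)
        assert cond.omega_n * taus[k] == pytest.approx(1.0, rel=0.15)

    def test_rocking_only_r1_uniform_across_residues(self, small_lattice):
        """Rigid-body motion relaxes every site equally (+-2%)."""
        proc = RockingProcess("restrained_diffusion", angular_stddev=0.15,
                              relaxation_time=2e-9, seed=14)
        traj = assemble_trajectory(small_lattice, proc, None, 20_000, 1e-9)
        cond = SpectrometerConditions()
        vs = nh_vector_series(traj, small_lattice)
        lags = log_lag_grid(1e-9, traj.length)
        rates = []
        for c in vector_correlation(vs, lags):
            fit = fit_multiexp(c, tau_cap=traj.length)
            rates.append(r1_nitrogen(fit, cond))
        rates = np.array(rates)
        assert rates.std() / rates.mean() < 0.02


class TestGlobalScaling:
    def test_identity_profiles(self):
        p = {i: 0.8 + 0.01 * i for i in range(10)}
        alpha, before, after = global_s2_scaling(p, p)
        assert alpha == pytest.approx(1.0)
        assert after == pytest.approx(0.0, abs=1e-12)

    def test_recovers_constructed_factor(self):
        a = {i: 0.95 - 0.02 * (i % 5) for i in range(20)}
        b = {i: v / 1.04 for i, v in a.items()}
        alpha, before, after = global_s2_scaling(a, b)
        assert alpha == pytest.approx(1.04, rel=1e-12)
        assert after < before

    def test_closed_form_equals_grid_search(self):
        rng = np.random.default_rng(4)
        a = {i: float(np.clip(0.9 + rng.normal(0, 0.03), 0, 1))
             for i in range(30)}
        b = {i: float(np.clip(a[i] / 1.05 + rng.normal(0, 0.01), 0, 1))
             for i in range(30)}
        alpha, _, _ = global_s2_scaling(a, b)
        grid = np.arange(0.8, 1.2, 1e-4)
        av = np.array([a[i] for i in range(30)])
        bv = np.array([b[i] for i in range(30)])
        cost = ((av[None, :] - grid[:, None] * bv[None, :]) ** 2).sum(axis=1)
        assert alpha == pytest.approx(grid[int(np.argmin(cost))], abs=1e-4)

    def test_too_few_shared_residues_rejected(self):
        with pytest.raises(ValueError):
            global_s2_scaling({1: 0.9, 2: 0.9}, {1: 0.9, 3: 0.9})
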