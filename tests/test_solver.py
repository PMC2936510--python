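"""Shape-equation solver: boundary conditions, invariants, convergence."""

import numpy as np
import pytest

import vesibud as vb
from vesibud.solver import TWO_PI


def _functional_on_arrays(s, psi, field, kappa):
    """Trapezoid evaluation of the sigma=0 objective for a psi-profile."""
    cosp = np.cos(psi)
    R = np.concatenate([[0.0], np.cumsum(0.5 * (cosp[1:] + cosp[:-1])
                                         * np.diff(s))])
    dpsi = np.gradient(psi, s)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = dpsi + np.sin(psi) / R
    H[0] = 2.0 * dpsi[0]
    U2 = (H - field(s)) ** 2
    return float(2.0 * np.pi * np.trapezoid(0.5 * kappa * U2 * R, s))


class TestRhsAndPoleStart:
    def test_flat_membrane_is_stationary(self, config):
        field = vb.capsid_field(0.08, 0.0)
        d = vb.shape_equations_rhs((0.0, 0.0, 100.0, 0.0, 0.0), 100.0,
                                   field, config)
        assert d[1] == 0.0      # psi'' = 0
        assert d[4] == 0.0      # gamma' = 0
        assert d[0] == 0.0 and d[2] == 1.0 and d[3] == 0.0

    def test_rhs_matches_numerical_derivative_of_solution(self, capsid25,
                                                          config):
        p = capsid25
        field = p.field
        # interior window away from the pole and the field discontinuity
        m = (p.s > 5.0) & (p.s < 20.0)
        ds_dt = np.array([
            vb.shape_equations_rhs(
                (p.psi[i], p.dpsi[i], p.R[i], p.z[i], p.gamma[i]),
                p.s[i], field, config)
            for i in np.nonzero(m)[0]])
        num = np.column_stack([np.gradient(a, p.s)[m] for a in
                               (p.psi, p.dpsi, p.R, p.z, p.gamma)])
        scale = np.max(np.abs(num), axis=0)
        np.testing.assert_allclose(ds_dt, num, atol=1e-3 * scale.max(),
                                   rtol=2e-3)

    def test_pole_series_flat_and_leading_order(self, config):
        field = vb.capsid_field(0.08, 0.0)
        psi, dpsi, R, z, gamma = vb.pole_series_start(0.0, 0.0, 1e-3, field,
                                                      config)
        assert (psi, R, z) == (0.0, 1e-3, 0.0)
        psi, dpsi, R, z, gamma = vb.pole_series_start(0.04, 0.0, 1e-3, field,
                                                      config)
        assert psi == pytest.approx(4e-5)
        assert R == pytest.approx(1e-3)
        assert dpsi == pytest.approx(0.04)

    def test_halving_pole_epsilon_does_not_move_solution(self, capsid25):
        cfg = vb.SolverConfig(pole_epsilon=5e-4)
        p2 = vb.solve_shape(capsid25.field, cfg, warm_start=capsid25)
        s = np.linspace(0.0, 490.0, 400)
        assert np.max(np.abs(p2.psi_at(s) - capsid25.psi_at(s))) < 1e-6
        E1 = vb.deformation_energy(capsid25)
        assert abs(vb.deformation_energy(p2) - E1) / E1 < 1e-4


class TestShooting:
    def test_flat_guess_is_exact_root(self, config):
        res = vb.shoot(vb.capsid_field(0.08, 0.0), config, (0.0, 0.0, 500.0))
        assert np.max(np.abs(res)) < 1e-9

    def test_residuals_shrink_toward_flat_root(self, config):
        field = vb.capsid_field(0.08, 0.0)
        norms = [np.linalg.norm(vb.shoot(field, config,
                                         (a, 0.0, 500.0 * (1 + a))))
                 for a in (4e-4, 2e-4, 1e-4)]
        assert norms[0] > norms[1] > norms[2] > 0

    def test_converged_root_residuals_below_tolerance(self, capsid25, config):
        res = vb.shoot(capsid25.field, config, capsid25.shoot_params)
        # dimensionless residual tolerance, converted to the mixed units
        assert abs(res[0]) < config.root_tol
        assert abs(res[1]) < config.root_tol * config.R0
        assert abs(res[2]) < config.root_tol * TWO_PI * config.kappa / config.R0


class TestSolveShape:
    def test_flat_solution_for_zero_field(self, flat_profile, config):
        p = flat_profile
        assert p.s1 == pytest.approx(config.R0)
        assert np.max(np.abs(p.psi)) == 0.0
        np.testing.assert_allclose(p.R, p.s)
        assert np.max(np.abs(p.z)) == 0.0
        assert vb.deformation_energy(p) == 0.0

    def test_profile_invariants(self, capsid25, capsid70, config):
        for p in (capsid25, capsid70):
            assert p.R[0] == 0.0 and p.psi[0] == 0.0
            assert abs(p.psi[-1]) < 1e-7
            assert abs(p.R[-1] - config.R0) < 1e-4
            assert np.min(p.R[1:]) > 0.0
            # R' = cos(psi), z' = sin(psi) along the grid
            m = (p.s > 1.0) & (p.s < p.s1 - 1.0)
            np.testing.assert_allclose(np.gradient(p.R, p.s)[m],
                                       np.cos(p.psi)[m], atol=2e-3)
            np.testing.assert_allclose(np.gradient(p.z, p.s)[m],
                                       np.sin(p.psi)[m], atol=2e-3)

    def test_large_capsid_is_overhung_small_is_shallow(self, capsid25,
                                                       capsid70):
        assert capsid70.max_psi() > 0.5 * np.pi          # overhang
        assert vb.neck_radius(capsid70, 70.0) < 0.4 * capsid70.max_R(70.0)
        assert capsid25.max_psi() < 0.5 * np.pi          # shallow cap
        assert vb.neck_radius(capsid25, 25.0) == pytest.approx(
            capsid25.max_R(25.0), rel=1e-3)

    def test_shell_field_produces_overhung_neck(self, shell_sweep):
        _table, profiles, summary = shell_sweep
        p = profiles[max(profiles)]
        assert p.max_psi() > 0.5 * np.pi
        assert "critical_s0" in summary

    def test_kappa_invariance_of_shape_at_zero_tension(self, capsid25):
        cfg = vb.SolverConfig(kappa=40.0)
        p2 = vb.solve_shape(vb.capsid_field(0.08, 25.0), cfg)
        s = np.linspace(0.0, 499.0, 500)
        assert np.max(np.abs(p2.psi_at(s) - capsid25.psi_at(s))) < 1e-7
        ratio = vb.deformation_energy(p2) / vb.deformation_energy(capsid25)
        assert ratio == pytest.approx(2.0, rel=1e-8)

    def test_continuation_failure_reports_last_fraction(self, config):
        # complete closure: a coat longer than the bud can accommodate
        with pytest.raises(vb.ContinuationFailure) as exc:
            vb.solve_shape(vb.capsid_field(0.08, 120.0), config)
        assert 0.0 <= exc.value.last_fraction < 1.0

    def test_mesh_convergence_under_tolerance_halving(self, capsid25):
        cfg = vb.SolverConfig(rel_tol=5e-9, abs_tol=5e-11)
        p2 = vb.solve_shape(capsid25.field, cfg, warm_start=capsid25)
        E1 = vb.deformation_energy(capsid25)
        assert abs(vb.deformation_energy(p2) - E1) / E1 < 1e-3


class TestHamiltonian:
    def test_flat_first_integral_vanishes(self, flat_profile):
        res = vb.hamiltonian_residual(flat_profile)
        assert np.max(np.abs(res)) == 0.0

    def test_corrected_residual_small_on_solutions(self, capsid25, epsin_b83):
        for p in (capsid25, epsin_b83):
            assert np.max(np.abs(vb.hamiltonian_residual(p))) < 1e-5

    def test_first_integral_piecewise_constant_for_capsid(self, capsid25):
        # within the constant-H0 coat and outside it, the raw first
        # integral is conserved (no source term where H0 is constant)
        p = capsid25
        cfg = p.config
        R0, kappa = cfg.R0, cfg.kappa
        Ut = p.H * R0 - p.field(p.s) * R0
        h = (p.R / R0 * p.dpsi * R0 * Ut - 0.5 * p.R / R0 * Ut ** 2
             + p.gamma * R0 / (TWO_PI * kappa) * np.cos(p.psi))
        inside = (p.s > 1.0) & (p.s < 24.0)
        outside = (p.s > 26.0)
        for m in (inside, outside):
            assert np.max(h[m]) - np.min(h[m]) < 1e-6


class TestMinimality:
    def test_solution_beats_perturbed_profiles(self, capsid25, epsin_b83):
        """Smooth constraint-compatible perturbations only raise the energy.

        Perturbations vanish at both ends; the rim pinning is restored by a
        flat zero-energy extension (sigma = 0), so the comparison is on the
        same footing as the constrained minimization.
        """
        rng = np.random.default_rng(42)
        for p in (capsid25, epsin_b83):
            kappa = p.config.kappa
            E0 = _functional_on_arrays(p.s, p.psi, p.field, kappa)
            win = np.sin(np.pi * p.s / p.s1)
            for _ in range(10):
                coeffs = rng.standard_normal(4)
                delta = win * sum(
                    c * np.sin((k + 1) * np.pi * p.s / p.s1)
                    for k, c in enumerate(coeffs))
                delta *= 0.01 / max(1e-12, np.max(np.abs(delta)))
                E = _functional_on_arrays(p.s, p.psi + delta, p.field, kappa)
                assert E >= E0 - 1e-6 * max(1.0, abs(E0))

    def test_first_variation_vanishes_at_solution(self, epsin_b83):
        """Central-difference directional derivatives are second order.

        This checks the variational content of the shape equations against
        an independent finite-difference evaluation of the discretized
        functional.
        """
        p = epsin_b83
        kappa = p.config.kappa
        rng = np.random.default_rng(7)
        win = np.sin(np.pi * p.s / p.s1)
        for _ in range(5):
            coeffs = rng.standard_normal(3)
            delta = win * sum(c * np.sin((k + 1) * np.pi * p.s / p.s1)
                              for k, c in enumerate(coeffs))
            delta /= max(1e-12, np.max(np.abs(delta)))
            t = 1e-3
            Ep = _functional_on_arrays(p.s, p.psi + t * delta, p.field, kappa)
            Em = _functional_on_arrays(p.s, p.psi - t * delta, p.field, kappa)
            E0 = _functional_on_arrays(p.s, p.psi, p.field, kappa)
            slope = abs(Ep - Em) / (2 * t)
            curvature = abs(Ep + Em - 2 * E0) / t ** 2
            assert slope < 0.05 * curvature * t + 1e-8


def test_profile_csv_roundtrip(tmp_path, capsid25):
    path = tmp_path / "profile.csv"
    capsid25.to_csv(path)
    p2 = vb.MembraneProfile.from_csv(path)
    np.testing.assert_allclose(p2.s, capsid25.s)
    np.testing.assert_allclose(p2.psi, capsid25.psi, atol=1e-12)
    np.testing.assert_allclose(p2.gamma, capsid25.gamma, atol=1e-12)
    assert p2.s1 == pytest.approx(capsid25.s1)
    assert p2.field == capsid25.field
    assert p2.config.kappa == capsid25.config.kappa
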