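"""Discretisation and integrator unit tests, checked against independent
oracles: polynomial exactness, analytic Laplacians, a high-order scipy
reference integrator, and a from-scratch dimensional PDE right-hand side."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from yeastcolony import (
    DimensionlessParameters,
    Grid,
    IntegratorError,
    State,
    degenerate_diffusion,
    initial_condition_1d,
    laplacian,
    perturbed_initial_condition_2d,
    run,
    stable_dt,
    step_euler,
)
from yeastcolony.solver import _rhs


def zero_state(grid: Grid) -> State:
    z = np.zeros(grid.shape)
    return State(0.0, z.copy(), z.copy(), z.copy(), z.copy())


class TestGrid:
    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="5 nodes"):
            Grid(x=np.linspace(0, 1, 4))

    def test_nonuniform_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            Grid(x=np.array([0.0, 0.5, 1.5, 2.0, 2.5]))

    def test_trapezoid_weights_sum_to_domain_measure(self):
        g = Grid.rectangle(10.0, 5.0, 0.5)
        assert g.quadrature_weights().sum() == pytest.approx(10.0 * 10.0)


class TestInitialConditions:
    def test_gaussian_inoculum(self):
        g = Grid.line(10.0, 0.5)
        s = initial_condition_1d(g)
        assert s.n[0] == pytest.approx(1.0)
        assert s.n[-1] == pytest.approx(np.exp(-100.0), abs=1e-40)
        assert s.g[0] == 1.0 and np.all(s.g == 1.0)
        assert np.sum((s.m1 + s.m2) * g.quadrature_weights()) == 0.0
        assert s.t == 0.0

    def test_nonfinite_profile_rejected(self):
        g = Grid.line(10.0, 0.5)
        with pytest.raises(ValueError, match="finite"):
            initial_condition_1d(g, profile=lambda x: np.where(x == 0, np.inf, 1.0))

    def test_perturbed_extension_delta_zero(self):
        g1 = Grid.line(20.0, 0.5)
        base = initial_condition_1d(g1)
        g2 = Grid.rectangle(20.0, 25.0, 0.5)
        q = 2 * np.pi / 50.0
        s = perturbed_initial_condition_2d(base, g1, g2, 0.0, q)
        for f, f0 in zip(s.fields(), base.fields()):
            np.testing.assert_allclose(f, np.tile(f0[:, None], (1, g2.y.size)))

    def test_perturbed_values_at_centre_and_wall(self):
        # delta=0.1: 1.1x at y=0; with Ly=100 and q=6pi/50 the wall sees
        # cos(6pi) = 1, again 1.1x
        g1 = Grid.line(20.0, 0.5)
        base = initial_condition_1d(g1)
        g2 = Grid.rectangle(20.0, 50.0, 0.5)
        q = 6 * np.pi / 50.0
        s = perturbed_initial_condition_2d(base, g1, g2, 0.1, q)
        j0 = np.argmin(np.abs(g2.y))
        np.testing.assert_allclose(s.n[:, j0], 1.1 * base.n)
        np.testing.assert_allclose(s.n[:, -1], 1.1 * base.n)
        assert s.t == 0.0

    def test_transverse_mean_equals_base(self):
        # cos integrates to zero over whole periods
        g1 = Grid.line(20.0, 0.5)
        base = initial_condition_1d(g1)
        g2 = Grid.rectangle(20.0, 25.0, 0.5)
        for k in (1, 2, 5):
            q = 2 * np.pi * k / 50.0
            s = perturbed_initial_condition_2d(base, g1, g2, 0.2, q)
            mean = np.trapezoid(s.n, g2.y, axis=1) / 50.0
            np.testing.assert_allclose(mean, base.n, atol=1e-12)

    def test_incompatible_wavenumber_rejected(self):
        g1 = Grid.line(20.0, 0.5)
        base = initial_condition_1d(g1)
        g2 = Grid.rectangle(20.0, 25.0, 0.5)
        with pytest.raises(ValueError, match="admissible"):
            perturbed_initial_condition_2d(base, g1, g2, 0.1, 0.123)


class TestLaplacian:
    def test_constant_field_zero(self):
        g = Grid.rectangle(5.0, 2.5, 0.5)
        np.testing.assert_allclose(laplacian(np.full(g.shape, 3.7), g), 0.0, atol=1e-12)

    def test_exact_on_quadratics_interior(self):
        g = Grid.line(10.0, 0.5)
        lap = laplacian(g.x**2, g)
        np.testing.assert_allclose(lap[1:-1], 2.0, rtol=1e-12)

    def test_second_order_convergence_on_cosine(self):
        L = 10.0
        errs = []
        for dx in (0.5, 0.25):
            g = Grid.line(L, dx)
            f = np.cos(np.pi * g.x / L)  # compatible: zero slope at both walls
            exact = -((np.pi / L) ** 2) * f
            errs.append(np.max(np.abs(laplacian(f, g) - exact)))
        ratio = errs[0] / errs[1]
        assert 3.4 < ratio < 4.6

    def test_boundary_closure_zero_normal_derivative(self):
        # ghost closure on cos(pi x / L) stays second-order at the walls too
        g = Grid.line(10.0, 0.25)
        f = np.cos(np.pi * g.x / 10.0)
        exact = -((np.pi / 10.0) ** 2) * f
        assert abs(laplacian(f, g)[0] - exact[0]) < 2e-3
        assert abs(laplacian(f, g)[-1] - exact[-1]) < 2e-3


class TestDegenerateDiffusion:
    def test_constant_zero(self):
        g = Grid.line(10.0, 0.5)
        np.testing.assert_allclose(degenerate_diffusion(np.full(g.shape, 2.0), g), 0.0, atol=1e-12)

    def test_linear_profile_interior(self):
        # div(n grad n) with n = x is d/dx(x * 1) = 1
        g = Grid.line(10.0, 0.5)
        np.testing.assert_allclose(degenerate_diffusion(g.x, g)[1:-1], 1.0, rtol=1e-12)

    def test_quadratic_profile_matches_analytic(self):
        # n = x^2: div(n grad n) = 0.5 (x^4)'' = 6 x^2, stencil error 2 dx^2
        g = Grid.line(10.0, 0.25)
        got = degenerate_diffusion(g.x**2, g)[1:-1]
        np.testing.assert_allclose(got, 6.0 * g.x[1:-1] ** 2, atol=2.1 * 0.25**2)

    def test_negative_density_rejected(self):
        g = Grid.line(10.0, 0.5)
        n = np.ones(g.shape)
        n[3] = -1e-6
        with pytest.raises(IntegratorError):
            degenerate_diffusion(n, g)


class TestStableDt:
    def test_formula_on_quiescent_state(self, default_params):
        g = Grid.line(10.0, 0.5)
        s = zero_state(g)
        s.g[:] = 0.0
        # only the nutrient's unit diffusivity is active: 0.2 * 0.25 / 2
        assert stable_dt(default_params, g, s) == pytest.approx(0.025)

    def test_doubling_dx_quadruples_dt(self, default_params):
        s1 = zero_state(Grid.line(10.0, 0.5))
        s2 = zero_state(Grid.line(10.0, 1.0))
        dt1 = stable_dt(default_params, Grid.line(10.0, 0.5), s1)
        dt2 = stable_dt(default_params, Grid.line(10.0, 1.0), s2)
        assert dt2 == pytest.approx(4 * dt1)

    def test_degenerate_diffusivity_scales_with_peak_density(self):
        p = DimensionlessParameters(D_n=0.47, C=0.0)
        g = Grid.line(10.0, 0.5)
        s = zero_state(g)
        s.n[:] = 4.0  # D_eff = 0.47 * 4 = 1.88 governs over the nutrient's 1
        assert stable_dt(p, g, s) == pytest.approx(0.2 * 0.25 / (2 * 1.88))
        s.n[:] = 2.0  # D_eff = 0.94 < 1: the nutrient bound takes over
        assert stable_dt(p, g, s) == pytest.approx(0.025)


class TestStepEuler:
    def test_zero_state_is_fixed_point(self, default_params):
        g = Grid.line(10.0, 0.5)
        s = step_euler(zero_state(g), default_params, g, 0.01)
        for f in s.fields():
            np.testing.assert_array_equal(f, 0.0)
        assert s.t == pytest.approx(0.01)

    def test_uniform_growth_step(self):
        # uniform fields: diffusion vanishes; g=1 closes both death windows
        p = DimensionlessParameters(Lambda1=0.5, Lambda2=0.5, g_2=1.0, g_dag=0.25, C=1.0)
        g = Grid.line(10.0, 0.5)
        ones = np.ones(g.shape)
        s = State(0.0, ones.copy(), 0 * ones, 0 * ones, ones.copy())
        s2 = step_euler(s, p, g, 0.01)
        np.testing.assert_allclose(s2.n, 1.01)
        np.testing.assert_allclose(s2.g, 0.99)
        np.testing.assert_array_equal(s2.m1, 0.0)
        np.testing.assert_array_equal(s2.m2, 0.0)

    def test_unstable_dt_rejected(self, default_params):
        g = Grid.line(10.0, 0.5)
        s = initial_condition_1d(g)
        with pytest.raises(ValueError, match="stability"):
            step_euler(s, default_params, g, 1.0)

    def test_first_order_convergence_against_rk45(self):
        """Halving dt halves the global error against a high-order reference
        solution of the same semi-discretisation."""
        p = DimensionlessParameters(Lambda1=0.5, Gamma1=0.5, K1=0.5)
        g = Grid.line(10.0, 0.5)
        ic = initial_condition_1d(g)

        def rhs_flat(t, y):
            n, m1, m2, gg = y.reshape(4, -1)
            s = State(t, n, m1, m2, gg)
            return np.concatenate(_rhs(s, p, g, "degenerate"))

        y0 = np.concatenate(ic.fields())
        ref = solve_ivp(rhs_flat, (0, 1.0), y0, method="RK45", rtol=1e-10, atol=1e-12)
        errs = []
        for dt in (0.01, 0.005):
            s = ic.copy()
            for _ in range(int(round(1.0 / dt))):
                s = step_euler(s, p, g, dt, enforce_stability=False)
            errs.append(np.max(np.abs(np.concatenate(s.fields()) - ref.y[:, -1])))
        assert 1.6 < errs[0] / errs[1] < 2.4


class TestRun:
    def test_zero_horizon_returns_initial_condition(self, default_params):
        g = Grid.line(10.0, 0.5)
        ic = initial_condition_1d(g)
        traj = run(default_params, g, ic, 0.0, snapshot_times=[0.0])
        assert len(traj) == 1
        np.testing.assert_array_equal(traj.snapshots[0].n, ic.n)

    def test_no_death_keeps_dead_fields_zero(self):
        p = DimensionlessParameters(Lambda1=0.0, Lambda2=0.0)
        g = Grid.line(20.0, 0.5)
        traj = run(p, g, initial_condition_1d(g), 10.0, snapshot_times=[0, 5, 10])
        for s in traj.snapshots:
            np.testing.assert_array_equal(s.m1, 0.0)
            np.testing.assert_array_equal(s.m2, 0.0)

    def test_determinism_bit_identical(self, default_params):
        g = Grid.line(20.0, 0.5)
        t1 = run(default_params, g, initial_condition_1d(g), 5.0, snapshot_times=[5.0])
        t2 = run(default_params, g, initial_condition_1d(g), 5.0, snapshot_times=[5.0])
        for a, b in zip(t1.snapshots[-1].fields(), t2.snapshots[-1].fields()):
            np.testing.assert_array_equal(a, b)

    def test_snapshot_times_recorded_and_increasing(self, default_params):
        g = Grid.line(20.0, 0.5)
        traj = run(default_params, g, initial_condition_1d(g), 10.0, snapshot_times=[0, 3, 7, 10])
        t = traj.times
        assert t[0] == 0.0
        assert np.all(np.diff(t) > 0)
        # each actual time is the first step at or beyond the request
        dt = traj.metadata["dt_final"]
        for req, actual in zip([3, 7, 10], t[1:]):
            assert req - 1e-9 <= actual < req + dt + 1e-9

    def test_conservation_without_breakdown(self):
        """With no breakdown the colony's bound nutrient C*(n+m1+m2)+g is a
        conserved quantity of the discrete scheme (trapezoid weights)."""
        p = DimensionlessParameters(Lambda1=0.5, Lambda2=0.3, g_1=0.0, g_2=0.9)
        g = Grid.line(30.0, 0.5)
        traj = run(p, g, initial_condition_1d(g), 25.0, snapshot_times=[0, 25])
        w = g.quadrature_weights()

        def functional(s):
            return np.sum(w * (p.C * (s.n + s.m1 + s.m2) + s.g))

        f0, f1 = functional(traj.snapshots[0]), functional(traj.snapshots[-1])
        assert abs(f1 - f0) / f0 < 1e-10

    def test_conservation_when_release_balances_consumption(self):
        # K_i = C makes breakdown nutrient-neutral in the same functional
        p = DimensionlessParameters(
            Lambda1=0.5, Lambda2=0.3, Gamma1=0.4, Gamma2=0.2, C=1.0, K1=1.0, K2=1.0
        )
        g = Grid.line(30.0, 0.5)
        traj = run(p, g, initial_condition_1d(g), 25.0, snapshot_times=[0, 25])
        w = g.quadrature_weights()

        def functional(s):
            return np.sum(w * (p.C * (s.n + s.m1 + s.m2) + s.g))

        assert abs(functional(traj.snapshots[-1]) - functional(traj.snapshots[0])) / functional(
            traj.snapshots[0]
        ) < 1e-10

    def test_half_domain_matches_full_domain(self, default_params):
        """Even initial data: solving on x > 0 with a symmetry plane equals
        the right half of the full-domain solution."""
        half = Grid.line(20.0, 0.5)
        full = Grid.line(20.0, 0.5, x_min=-20.0)
        t_half = run(default_params, half, initial_condition_1d(half), 10.0, snapshot_times=[10.0])
        t_full = run(default_params, full, initial_condition_1d(full), 10.0, snapshot_times=[10.0])
        mid = full.x.size // 2
        for fh, ff in zip(t_half.snapshots[-1].fields(), t_full.snapshots[-1].fields()):
            np.testing.assert_allclose(fh, ff[mid:], atol=1e-10)

    def test_more_nutrient_never_retards_the_front(self):
        """Comparison-principle spot check: raising the initial nutrient
        pointwise cannot slow the no-death colony."""
        from yeastcolony import front_position

        p = DimensionlessParameters()
        g = Grid.line(40.0, 0.5)
        lo = initial_condition_1d(g)
        hi = lo.copy()
        hi.g[:] = 1.25
        snaps = [10.0, 20.0, 30.0]
        t_lo = run(p, g, lo, 30.0, snapshot_times=snaps)
        t_hi = run(p, g, hi, 30.0, snapshot_times=snaps)
        for s_lo, s_hi in zip(t_lo.snapshots[1:], t_hi.snapshots[1:]):
            assert front_position(g.x, s_hi.n) >= front_position(g.x, s_lo.n)

    def test_dimensional_pde_rescales_onto_dimensionless_solution(self):
        """Integrating the dimensional system with an independently written
        right-hand side and rescaling matches the dimensionless solver."""
        from yeastcolony import DimensionalParameters, nondimensionalize

        p = DimensionalParameters(
            D_n=0.2, D_g=1.0, D_m1=0.01, D_m2=0.02, alpha=2.0, c=0.8,
            lambda1=0.6, lambda2=1.5, g_dag=0.125, g_1=0.05, g_2=0.45,
            gamma1=0.3, gamma2=0.2, k1=0.4, k2=0.7, N0=2.0, G0=0.5,
        )
        nd = nondimensionalize(p)
        grid = Grid.line(8.0, 0.25)
        ic = initial_condition_1d(grid)
        t_end = 2.0

        # dimensionless side, integrated by scipy on the package's RHS
        def rhs_dimless(t, y):
            n, m1, m2, gg = y.reshape(4, -1)
            return np.concatenate(_rhs(State(t, n, m1, m2, gg), nd.params, grid, "degenerate"))

        sol = solve_ivp(
            rhs_dimless, (0, t_end), np.concatenate(ic.fields()),
            method="RK45", rtol=1e-9, atol=1e-11,
        )
        n_dl, m1_dl, m2_dl, g_dl = sol.y[:, -1].reshape(4, -1)

        # dimensional side: from-scratch MOL right-hand side on x* = Ls * x
        dxs = nd.space_scale * grid.dx

        def lap_s(f):
            pad = np.pad(f, 1, mode="reflect")
            return (pad[:-2] - 2 * f + pad[2:]) / dxs**2

        def rhs_dim(t, y):
            n, m1, m2, gg = y.reshape(4, -1)
            acd = p.lambda1 * n * np.maximum(p.g_dag - gg, 0.0)
            rcd = p.lambda2 * n * np.where(
                (gg > p.g_1) & (gg < p.g_2), (gg - p.g_1) * (p.g_2 - gg), 0.0
            )
            dn = p.D_n * 0.5 * lap_s(n * n) + p.alpha * n * gg - acd - rcd
            dm1 = p.D_m1 * lap_s(m1) + acd - p.gamma1 * m1
            dm2 = p.D_m2 * lap_s(m2) + rcd - p.gamma2 * m2
            dg = (
                p.D_g * lap_s(gg) - p.c * p.alpha * n * gg
                + p.k1 * p.gamma1 * m1 + p.k2 * p.gamma2 * m2
            )
            return np.concatenate([dn, dm1, dm2, dg])

        y0_dim = np.concatenate([p.N0 * ic.n, p.N0 * ic.m1, p.N0 * ic.m2, p.G0 * ic.g])
        sol_dim = solve_ivp(
            rhs_dim, (0, t_end * nd.time_scale), y0_dim,
            method="RK45", rtol=1e-9, atol=1e-11,
        )
        n_d, m1_d, m2_d, g_d = sol_dim.y[:, -1].reshape(4, -1)
        np.testing.assert_allclose(n_d / p.N0, n_dl, rtol=2e-6, atol=1e-8)
        np.testing.assert_allclose(m1_d / p.N0, m1_dl, rtol=2e-6, atol=1e-8)
        np.testing.assert_allclose(m2_d / p.N0, m2_dl, rtol=2e-6, atol=1e-8)
        np.testing.assert_allclose(g_d / p.G0, g_dl, rtol=2e-6, atol=1e-8)
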