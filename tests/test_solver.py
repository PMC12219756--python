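import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cpcphase import (
    ModelParameters,
    NoiseSpec,
    NumericsConfig,
    OrderParameterField,
    SolverDivergenceError,
    discrete_energy,
    integrate,
    laplacian_neumann,
    noisy_uniform_field,
    rhs,
    rk4_step,
    stability_dt_bound,
)
from conftest import uniform_field


def scalar_rk4(u0, rate_fn, dt, nsteps):
    """Reference RK4 on the scalar reaction ODE."""
    u = u0
    for _ in range(nsteps):
        k1 = rate_fn(u)
        k2 = rate_fn(u + 0.5 * dt * k1)
        k3 = rate_fn(u + 0.5 * dt * k2)
        k4 = rate_fn(u + dt * k3)
        u = u + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return u


def closed_form_uniform(phi0, t, epsilon=0.1):
    """Exact solution of phi' = eps**-2 * phi(1-phi)(phi-1/2), uniform case.

    Logistic substitution v = (phi - 1/2)**2:
    v' = 2 eps**-2 v (1/4 - v), hence
    v(t) = (1/4) / (1 + ((1/(4 v0)) - 1) exp(-t / (2 eps**2))).
    """
    v0 = (phi0 - 0.5) ** 2
    v = 0.25 / (1.0 + (1.0 / (4.0 * v0) - 1.0) * np.exp(-t / (2.0 * epsilon ** 2)))
    return 0.5 + np.sign(phi0 - 0.5) * np.sqrt(v)


class TestLaplacian:
    def test_constant_field_gives_exact_zero(self):
        assert np.all(laplacian_neumann(uniform_field(0.37, N=16)) == 0.0)

    def test_unit_spike_stencil(self):
        # h = 0.5 -> 1/h^2 = 4: -16 at the spike, +4 at the 4-neighbors
        n = 8  # L=2 gives h=0.5
        vals = np.zeros((n, n))
        vals[4, 4] = 1.0
        lap = laplacian_neumann(OrderParameterField(vals, L=2.0))
        expected = np.zeros((n, n))
        expected[4, 4] = -16.0
        expected[3, 4] = expected[5, 4] = expected[4, 3] = expected[4, 5] = 4.0
        np.testing.assert_array_equal(lap, expected)

    def test_second_order_convergence_on_analytic_function(self):
        # g = cos(pi x / L) cos(pi y / L) is Neumann-compatible and even about
        # the boundary, so the mirrored ghost cells are exact.
        L = 1.0
        errors = {}
        for n in (64, 128, 256):
            fld = uniform_field(0.0, N=n, L=L)
            x = fld.cell_centers()
            g = np.cos(np.pi * x[:, None] / L) * np.cos(np.pi * x[None, :] / L)
            exact = -2.0 * (np.pi / L) ** 2 * g
            fld.values[:] = g
            errors[n] = np.max(np.abs(laplacian_neumann(fld) - exact))
        order1 = np.log2(errors[64] / errors[128])
        order2 = np.log2(errors[128] / errors[256])
        assert order1 >= 1.9
        assert order2 >= 1.9

    def test_rejects_non_square_grid(self):
        with pytest.raises(ValueError, match="square"):
            OrderParameterField(np.zeros((4, 6)))


class TestRhs:
    def test_uniform_at_threshold_is_stationary(self, water_params):
        fld = uniform_field(0.5)
        assert np.all(rhs(fld, 0.1, water_params) == 0.0)

    def test_after_switch_off_only_reaction_remains(self, water_params):
        fld = noisy_uniform_field(NoiseSpec(seed=1), N=16)
        out = rhs(fld, water_params.T, water_params)
        expected = (fld.values * (1 - fld.values) * (fld.values - 0.5)
                    * water_params.epsilon ** -2)
        np.testing.assert_allclose(out, expected, rtol=1e-15)

    def test_uniform_value_hand_arithmetic(self, water_params):
        # eps^-2 * f(0.6) = 100 * 0.6 * 0.4 * 0.1 = 2.4; Laplacian of uniform is 0
        out = rhs(uniform_field(0.6), 0.0, water_params)
        np.testing.assert_allclose(out, 2.4, rtol=1e-14)


class TestRk4Step:
    @pytest.mark.parametrize("value", [0.0, 0.5, 1.0])
    def test_uniform_fixed_points_bit_stable(self, value, water_params):
        fld = uniform_field(value)
        out = rk4_step(fld, 0.1, 1e-3, water_params)
        assert np.array_equal(out.values, fld.values)

    def test_matches_scalar_rk4_on_uniform_field(self, water_params):
        dt = 1e-3
        out = rk4_step(uniform_field(0.6), 0.0, dt, water_params)
        ref = scalar_rk4(0.6, lambda u: 100.0 * u * (1 - u) * (u - 0.5), dt, 1)
        np.testing.assert_allclose(out.values, ref, rtol=1e-15)

    def test_reflection_symmetry_preserved(self, water_params):
        rng = np.random.default_rng(0)
        half = 0.5 + 0.01 * rng.standard_normal((16, 8))
        vals = np.concatenate([half, half[:, ::-1]], axis=1)
        out = rk4_step(OrderParameterField(vals), 0.0, 1e-4, water_params).values
        np.testing.assert_allclose(out, out[:, ::-1], atol=1e-14)

    def test_step_straddling_switch_time_refused(self, water_params):
        fld = uniform_field(0.6)
        with pytest.raises(ValueError, match="straddles"):
            rk4_step(fld, 0.7995, 1e-3, water_params)
        # landing exactly on T is allowed
        rk4_step(fld, 0.799, 1e-3, water_params)


class TestIntegrate:
    def test_stationary_at_threshold(self, water_params, fast_config):
        series = integrate(uniform_field(0.5, N=32), water_params, fast_config)
        assert series.times == [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        for _, fld in series.entries:
            assert np.all(fld.values == 0.5)

    def test_uniform_trajectory_matches_closed_form(self, water_params):
        n = 32
        cfg = NumericsConfig(N=n)  # dt = 0.1/N^2
        series = integrate(uniform_field(0.6, N=n), water_params, cfg)
        for t, fld in series.entries[1:]:
            assert np.all(fld.values == fld.values[0, 0])  # stays uniform
            assert fld.values[0, 0] == pytest.approx(
                closed_form_uniform(0.6, t), abs=1e-8)

    def test_uniform_trajectory_matches_adaptive_oracle_general_threshold(self):
        params = ModelParameters(phi_bar=0.45)
        n = 32
        series = integrate(uniform_field(0.35, N=n), params, NumericsConfig(N=n))
        sol = solve_ivp(
            lambda t, u: 100.0 * u * (1 - u) * (u - 0.45), (0.0, 1.0), [0.35],
            method="DOP853", rtol=1e-12, atol=1e-14, dense_output=True,
        )
        for t, fld in series.entries[1:]:
            assert fld.values[0, 0] == pytest.approx(float(sol.sol(t)[0]), abs=1e-8)

    def test_matches_repeated_rk4_steps(self, water_params):
        # cross-checks the compiled segment kernel against the numpy reference
        n = 12
        initial = noisy_uniform_field(NoiseSpec(seed=4), N=n)
        cfg = NumericsConfig(N=n, dt=2e-4, t_end=0.9,
                             snapshot_times=(0.3, 0.85))
        series = integrate(initial, water_params, cfg)
        fld = initial.copy()
        t = 0.0
        recorded = {}
        # same segment layout: boundaries at snapshots, T=0.8 and t_end
        for b in (0.3, 0.8, 0.85, 0.9):
            nsteps = max(1, int(np.ceil((b - t) / 2e-4 - 1e-9)))
            for k in range(nsteps):
                dt = 2e-4 if k < nsteps - 1 else b - t - (nsteps - 1) * 2e-4
                fld = rk4_step(fld, t + k * 2e-4, dt, water_params)
            fld.t = t = b
            recorded[b] = fld.values.copy()
        for ts in (0.3, 0.85):
            np.testing.assert_allclose(series.field_at(ts).values, recorded[ts],
                                       rtol=1e-13, atol=1e-15)

    def test_snapshots_on_noisy_reference_run_scaled(self, water_params):
        series = integrate(noisy_uniform_field(NoiseSpec(seed=1), N=32),
                           water_params, NumericsConfig(N=32))
        assert series.times == [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        assert all(np.all(np.isfinite(f.values)) for _, f in series.entries)

    def test_range_preserved_from_bracketed_initial_data(self, water_params):
        n = 32
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.25, 0.75, (n, n))
        h = 2.0 / n
        dt = stability_dt_bound(water_params, h)
        cfg = NumericsConfig(N=n, dt=dt, t_end=1.0, dt_policy="stability-checked")
        series = integrate(OrderParameterField(vals), water_params, cfg)
        for _, fld in series.entries:
            assert fld.values.min() >= -1e-6
            assert fld.values.max() <= 1.0 + 1e-6
            assert fld.range_violation() == 0.0

    def test_post_switch_dynamics_are_pointwise_monotone(self, water_params):
        # for t >= T each cell decouples: phi > phi_bar rises, phi < phi_bar falls
        n = 32
        series = integrate(noisy_uniform_field(NoiseSpec(seed=2), N=n),
                           water_params, NumericsConfig(N=n))
        at_T = series.field_at(0.8).values
        final = series.field_at(1.0).values
        up = at_T > water_params.phi_bar
        down = at_T < water_params.phi_bar
        assert np.all(final[up] >= at_T[up] - 1e-12)
        assert np.all(final[down] <= at_T[down] + 1e-12)

    def test_divergent_step_aborts_with_error(self, water_params):
        cfg = NumericsConfig(N=16, dt=0.3, t_end=1.0)  # wildly unstable
        with pytest.raises(SolverDivergenceError, match="non-finite"):
            integrate(noisy_uniform_field(NoiseSpec(seed=1), N=16),
                      water_params, cfg)

    def test_stability_policy_rejects_large_dt(self, water_params):
        cfg = NumericsConfig(N=16, dt=0.05, t_end=1.0, dt_policy="stability-checked")
        with pytest.raises(ValueError, match="stability bound"):
            integrate(uniform_field(0.6, N=16), water_params, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="sorted"):
            NumericsConfig(snapshot_times=(0.4, 0.2))
        with pytest.raises(ValueError, match="within"):
            NumericsConfig(snapshot_times=(0.5, 2.0))
        with pytest.raises(ValueError, match="dt_policy"):
            NumericsConfig(dt_policy="adaptive")


class TestDiscreteEnergy:
    def test_pure_wells_have_zero_energy(self, water_params):
        for v in (0.0, 1.0):
            assert discrete_energy(uniform_field(v, N=16), 0.0, water_params) == 0.0

    def test_uniform_liquid_energy_value(self, water_params):
        # eps^-2 * W(0.5) * |Omega| = 100 * (1/64) * 4 = 6.25, any N
        e = discrete_energy(uniform_field(0.5, N=20), 0.0, water_params)
        assert e == pytest.approx(6.25, rel=1e-12)

    def test_energy_non_increasing_along_trajectory(self, water_params):
        n = 32
        h = 2.0 / n
        dt = stability_dt_bound(water_params, h)
        fld = noisy_uniform_field(NoiseSpec(seed=3), N=n)
        t, e_prev = 0.0, discrete_energy(fld, 0.0, water_params)
        for _ in range(400):  # constant-D segment (stays below T=0.8)
            fld = rk4_step(fld, t, dt, water_params)
            t += dt
            e = discrete_energy(fld, t, water_params)
            assert e <= e_prev + 1e-10
            e_prev = e


class TestGridConvergence:
    @staticmethod
    def _solve(n, L=1.0, t_final=0.5):
        params = ModelParameters()
        fld = uniform_field(0.5, N=n, L=L)
        x = fld.cell_centers()
        fld.values[:] = 0.5 + 1e-6 * np.cos(np.pi * x[:, None] / L) * \
            np.cos(np.pi * x[None, :] / L)
        cfg = NumericsConfig(N=n, dt=1e-3, t_end=t_final, snapshot_times=(t_final,),
                             dt_policy="stability-checked")
        return integrate(fld, params, cfg).field_at(t_final).values

    @staticmethod
    def _restrict(u):
        # 2x2 block average: maps a 2N-grid solution onto the nested N grid
        return 0.25 * (u[::2, ::2] + u[1::2, ::2] + u[::2, 1::2] + u[1::2, 1::2])

    def test_solution_converges_at_second_order_in_h(self):
        # same dt for all grids so the differences isolate the spatial error
        u64, u128, u256 = (self._solve(n) for n in (64, 128, 256))
        e1 = np.max(np.abs(u64 - self._restrict(u128)))
        e2 = np.max(np.abs(u128 - self._restrict(u256)))
        order = np.log2(e1 / e2)
        assert order >= 1.9
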