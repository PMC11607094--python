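import numpy as np
import pytest

from nacsim.constants import THETA
from nacsim.grid import ScalarField, make_grid
from nacsim.mechanics import MechConstants
from nacsim.pharmacodynamics import PDParams
from nacsim.regimen import standard_regimen
from nacsim.sensitivity import lhs, table1_space
from nacsim.solver import ModelParams, simulate, simulate_batch, step


def const_field(grid, value):
    return ScalarField(grid, np.full(grid.shape, float(value)))


def logistic_exact(n0, rho, theta, t):
    return theta * n0 / (n0 + (theta - n0) * np.exp(-rho * t))


def base_params(D0=2e-4, rho0=0.025, E1n=0.0, dm1=0.0, mech=None):
    pd = PDParams(rho0=rho0, h1=1.5, h2=1.2, C1=0.01, C2=5.0, E1n=E1n,
                  E2n=0.0, a1=1.0, a2=1.0, beta=0.0)
    kwargs = {} if mech is None else {"mech": mech}
    return ModelParams(D0=D0, pd=pd, dm1=dm1, g1=0.5, dm2=0.0, g2=2.0, **kwargs)


class TestStep:
    def test_mass_conserved_under_pure_diffusion(self, well_scenario):
        # zero-flux + rho = 0: the implicit step conserves total mass
        grid = well_scenario.grid
        rng = np.random.default_rng(0)
        D = ScalarField(grid, 10 ** rng.uniform(-4, -1, grid.shape))
        N = well_scenario.N0
        for _ in range(5):
            N2 = step(N, D, const_field(grid, 0.0), dt=0.25)
            m0, m1 = N.values.sum(), N2.values.sum()
            assert abs(m1 - m0) / m0 < 1e-8
            N = N2

    def test_logistic_closed_form_with_zero_diffusion(self, grid10):
        # D = 0 decouples voxels; the implicit update must track the exact
        # logistic solution at the scheme's first-order accuracy in dt
        rho, T = 0.08, 10.0
        n0 = 0.3 * THETA
        errs = []
        for dt in (0.5, 0.25, 0.125):
            N = const_field(grid10, n0)
            D = const_field(grid10, 0.0)
            for _ in range(int(round(T / dt))):
                N = step(N, D, const_field(grid10, rho), dt=dt)
            exact = logistic_exact(n0, rho, THETA, T)
            errs.append(abs(N.values[0, 0, 0] - exact) / exact)
        # first-order convergence: halving dt roughly halves the error
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.3)
        assert errs[1] / errs[2] == pytest.approx(2.0, rel=0.3)
        assert errs[2] < 2e-3

    def test_carrying_capacity_is_fixed_point(self, grid10):
        N = const_field(grid10, THETA)
        out = step(N, const_field(grid10, 1e-3), const_field(grid10, 0.05), 0.25)
        np.testing.assert_array_equal(out.values, N.values)

    def test_zero_density_is_fixed_point(self, grid10):
        out = step(const_field(grid10, 0.0), const_field(grid10, 1e-3),
                   const_field(grid10, 0.05), 0.25)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_preconditions(self, grid10):
        N = const_field(grid10, 1.0)
        with pytest.raises(ValueError):
            step(N, N, N, dt=0.0)
        other = const_field(make_grid((4, 4, 4), (1, 1, 1)), 1.0)
        with pytest.raises(ValueError):
            step(N, other, N, dt=0.25)

    def test_matches_dense_newton_reference(self):
        """Double-entry check of one implicit step against an independent
        dense-matrix Newton solve of the same discrete system."""
        g = make_grid((5, 4, 4), (2.0, 1.5, 1.0))
        rng = np.random.default_rng(42)
        n = rng.uniform(0, 0.8 * THETA, g.shape)
        Dv = 10 ** rng.uniform(-3, -1, g.shape)
        rho = rng.uniform(-0.3, 0.1, g.shape)
        dt = 0.25

        shape = g.shape
        nvox = np.prod(shape)
        idx = np.arange(nvox).reshape(shape)
        L = np.zeros((nvox, nvox))
        for axis, h in enumerate(g.spacing):
            for sl in range(shape[axis] - 1):
                lo = np.take(idx, sl, axis=axis).ravel()
                hi = np.take(idx, sl + 1, axis=axis).ravel()
                dlo = np.take(Dv, sl, axis=axis).ravel()
                dhi = np.take(Dv, sl + 1, axis=axis).ravel()
                f = 0.5 * (dlo + dhi) / h ** 2
                L[lo, hi] += f
                L[hi, lo] += f
                L[lo, lo] -= f
                L[hi, hi] -= f

        x = n.ravel().copy()
        r = rho.ravel()
        for _ in range(50):
            F = (x - n.ravel()) / dt - L @ x - r * x * (1 - x / THETA)
            if np.linalg.norm(F) <= 1e-13 * np.linalg.norm(n.ravel() / dt):
                break
            J = np.eye(nvox) / dt - L - np.diag(r * (1 - 2 * x / THETA))
            x = x - np.linalg.solve(J, F)

        out = step(ScalarField(g, n), ScalarField(g, Dv), ScalarField(g, rho), dt)
        np.testing.assert_allclose(out.values.ravel(), x, rtol=1e-8, atol=1e-6)


class TestSimulate:
    def test_untreated_growth_is_monotone(self, small_scenario):
        reg = standard_regimen("dox_cyc")
        traj = simulate(small_scenario, base_params(), reg)
        assert traj.times[-1] == 56.0
        assert np.all(np.diff(traj.NT) > 0)

    def test_strong_drug_shrinks_tumor(self, small_scenario):
        reg = standard_regimen("dox_cyc")
        params = base_params(E1n=-5.0, dm1=300.0)
        traj = simulate(small_scenario, params, reg)
        assert traj.NT[-1] < traj.NT[0]

    def test_decoupled_limit_matches_plain_reaction_diffusion(self, small_scenario):
        """With no drug and (numerically) no stress-diffusivity coupling the
        model reduces to an uncoupled reaction-diffusion run; compare with an
        independent dense-matrix implicit integrator."""
        mech = MechConstants(gammaN=1e-14)
        params = base_params(D0=5e-3, mech=mech)
        reg = standard_regimen("dox_cyc")
        dt, n_steps = 0.25, 16
        traj = simulate(small_scenario, params, reg, dt=dt,
                        snapshot_times=(n_steps * dt,))

        g = small_scenario.grid
        shape = g.shape
        nvox = np.prod(shape)
        idx = np.arange(nvox).reshape(shape)
        L = np.zeros((nvox, nvox))
        for axis, h in enumerate(g.spacing):
            for sl in range(shape[axis] - 1):
                lo = np.take(idx, sl, axis=axis).ravel()
                hi = np.take(idx, sl + 1, axis=axis).ravel()
                f = 0.5 * (params.D0 + params.D0) / h ** 2
                L[lo, hi] += f
                L[hi, lo] += f
                L[lo, lo] -= f
                L[hi, hi] -= f
        x = small_scenario.N0.values.ravel().copy()
        rho0 = params.pd.rho0
        for _ in range(n_steps):
            xb = x.copy()
            for _new in range(30):
                F = (x - xb) / dt - L @ x - rho0 * x * (1 - x / THETA)
                if np.linalg.norm(F) <= 1e-12 * np.linalg.norm(xb / dt):
                    break
                J = np.eye(nvox) / dt - L - np.diag(rho0 * (1 - 2 * x / THETA))
                x = x - np.linalg.solve(J, F)
        snap = traj.snapshots[n_steps * dt].values.ravel()
        np.testing.assert_allclose(snap, x, rtol=1e-9, atol=1e-4)

    def test_bitwise_determinism(self, small_scenario):
        reg = standard_regimen("dox_cyc")
        params = base_params(E1n=-2.0, dm1=50.0)
        t1 = simulate(small_scenario, params, reg)
        t2 = simulate(small_scenario, params, reg)
        assert np.array_equal(t1.final.values, t2.final.values)
        assert np.array_equal(t1.VT, t2.VT)

    def test_batch_equals_solo_bitwise(self, small_scenario):
        """Chunking a campaign must not alter any run's arithmetic."""
        rows = lhs(table1_space("dox_cyc"), 8, seed=5)
        reg = standard_regimen("dox_cyc")
        batch = simulate_batch(small_scenario, rows, reg)
        solo = simulate_batch(small_scenario, rows[3:4], reg)
        assert np.array_equal(batch.final[3], solo.final[0])
        assert np.array_equal(batch.NT[3], solo.NT[0])

    def test_boundedness_over_parameter_space_draws(self, well_scenario):
        # smoke suite over the full sampling ranges: density stays in [0, theta]
        rows = lhs(table1_space("dox_cyc"), 100, seed=17)
        reg = standard_regimen("dox_cyc")
        res = simulate_batch(well_scenario, rows, reg)
        assert res.final.min() >= 0.0
        assert res.final.max() <= THETA
        assert np.all(res.NT >= 0) and np.all(res.VT >= 0)

    def test_temporal_self_convergence_first_order(self, small_scenario):
        params = base_params(D0=5e-3, rho0=0.05)
        reg = standard_regimen("dox_cyc")
        T = 8.0
        finals = {}
        for dt in (1.0, 0.5, 0.25, 0.125):
            short = simulate(small_scenario, params, reg, dt=dt, mech_every=1,
                             snapshot_times=(T,))
            finals[dt] = short.snapshots[T].values
        e1 = np.abs(finals[1.0] - finals[0.125]).max()
        e2 = np.abs(finals[0.5] - finals[0.125]).max()
        e3 = np.abs(finals[0.25] - finals[0.125]).max()
        assert e1 / e2 == pytest.approx(2.0, rel=0.4)
        assert e2 > e3

    def test_horizon_divisibility_enforced(self, small_scenario):
        reg = standard_regimen("dox_cyc")
        with pytest.raises(ValueError):
            simulate(small_scenario, base_params(), reg, dt=0.3)

    def test_snapshots_and_qoi_series(self, small_scenario):
        reg = standard_regimen("dox_cyc")
        traj = simulate(small_scenario, base_params(), reg,
                        snapshot_times=(0.0, 28.0, 56.0))
        assert set(traj.snapshots) == {0.0, 28.0, 56.0}
        assert len(traj.times) == len(traj.VT) == len(traj.NT) == 225
        np.testing.assert_array_equal(traj.snapshots[0.0].values,
                                      small_scenario.N0.values)
        np.testing.assert_array_equal(traj.snapshots[56.0].values,
                                      traj.final.values)


class TestModelParams:
    def test_vector_round_trip(self):
        p = base_params(E1n=-1.0, dm1=10.0)
        v = p.to_vector()
        assert v.shape == (15,)
        back = ModelParams.from_vector(v)
        np.testing.assert_array_equal(back.to_vector(), v)

    def test_bad_vector_shape(self):
        with pytest.raises(ValueError):
            ModelParams.from_vector(np.zeros(14))
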