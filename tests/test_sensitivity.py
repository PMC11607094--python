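import numpy as np
import pytest
from scipy import stats

from nacsim.errors import UndefinedResultError
from nacsim.regimen import standard_regimen
from nacsim.sensitivity import (EPS_S, bootstrap_ci, lhs,
                                reduced_model_comparison, run_sa,
                                saltelli_design, table1_space, total_effects)
from nacsim.solver import PARAM_ORDER, simulate_batch


def jansen_reference(YA, YB, YAB):
    """Independent transcription of the total-effects estimator."""
    n_s = len(YA)
    pooled = list(YA) + list(YB)
    mean = sum(pooled) / (2 * n_s)
    var = sum((y - mean) ** 2 for y in pooled) / (2 * n_s)
    acc = sum((a - ab) ** 2 for a, ab in zip(YA, YAB))
    return acc / (2 * n_s * var)


class TestParameterSpace:
    def test_dox_effect_bounds(self):
        space = table1_space("dox_cyc")
        row = dict(zip(space.names, space.rows))["E1n"]
        assert (row.lower, row.upper) == (-5.0, 0.5)
        assert row.scale == "regular"

    def test_ptx_decay_bounds(self):
        space = table1_space("ptx_cpt")
        row = dict(zip(space.names, space.rows))["g2"]
        assert (row.lower, row.upper) == (0.1, 0.2)

    def test_schema(self):
        for kind in ("dox_cyc", "ptx_cpt"):
            space = table1_space(kind)
            assert len(space.rows) == 15
            assert space.names == PARAM_ORDER
            assert all(r.scale in ("log", "regular") for r in space.rows)
            assert all(r.lower < r.upper for r in space.rows)

    def test_regimen_specific_rows_differ(self):
        d = dict(zip(PARAM_ORDER, table1_space("dox_cyc").rows))
        p = dict(zip(PARAM_ORDER, table1_space("ptx_cpt").rows))
        assert d["h1"].upper == 25.0 and p["h1"].upper == 6.3
        assert d["g2"].lower == 1.7 and p["g2"].lower == 0.1
        assert d["D0"] == p["D0"]  # shared baseline rows

    def test_midpoints(self):
        space = table1_space("dox_cyc")
        mids = dict(zip(space.names, space.midpoints()))
        assert mids["rho0"] == pytest.approx(1e-2)          # geometric
        assert mids["E1n"] == pytest.approx(-2.25)          # arithmetic

    def test_unknown_regimen(self):
        with pytest.raises(ValueError):
            table1_space("ac_t")


class TestLHS:
    def test_stratification(self):
        space = table1_space("dox_cyc")
        n_s = 64
        sample = lhs(space, n_s, seed=3)
        for i, row in enumerate(space.rows):
            col = sample[:, i]
            assert col.min() >= row.lower and col.max() <= row.upper
            if row.scale == "log":
                unit = (np.log10(col) - np.log10(row.lower)) / (
                    np.log10(row.upper) - np.log10(row.lower))
            else:
                unit = (col - row.lower) / (row.upper - row.lower)
            strata = np.floor(unit * n_s).astype(int)
            assert sorted(strata) == list(range(n_s))  # one per stratum

    def test_deterministic_per_seed(self):
        space = table1_space("ptx_cpt")
        assert np.array_equal(lhs(space, 16, 9), lhs(space, 16, 9))
        assert not np.array_equal(lhs(space, 16, 9), lhs(space, 16, 10))

    def test_log_column_uniform_in_log10(self):
        space = table1_space("dox_cyc")
        sample = lhs(space, 10_000, seed=1)
        logs = np.log10(sample[:, PARAM_ORDER.index("D0")])
        ks = stats.kstest(logs, stats.uniform(loc=-6, scale=5).cdf)
        assert ks.pvalue > 0.01

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            lhs(table1_space("dox_cyc"), 1, seed=0)


class TestSaltelliDesign:
    def test_column_swap(self):
        rng = np.random.default_rng(0)
        A, B = rng.random((20, 15)), rng.random((20, 15))
        design = saltelli_design(A, B)
        assert len(design.AB) == 15
        for i, M in enumerate(design.AB):
            np.testing.assert_array_equal(M[:, i], B[:, i])
            other = [j for j in range(15) if j != i]
            np.testing.assert_array_equal(M[:, other], A[:, other])

    def test_total_design_size(self):
        A = np.zeros((1000, 15))
        design = saltelli_design(A, A.copy())
        assert design.design_rows().shape == (17000, 15)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            saltelli_design(np.zeros((4, 15)), np.zeros((5, 15)))


class TestTotalEffects:
    def test_identical_columns_give_zero(self):
        rng = np.random.default_rng(1)
        YA, YB = rng.random(50), rng.random(50)
        assert total_effects(YA, YB, YA.copy()) == 0.0

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(2)
        YA, YB, YAB = rng.random(200), rng.random(200), rng.random(200)
        got = total_effects(YA, YB, YAB)
        assert got == pytest.approx(jansen_reference(YA, YB, YAB), rel=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        YA, YB, YAB = rng.random(100), rng.random(100), rng.random(100)
        s0 = total_effects(YA, YB, YAB)
        s1 = total_effects(5 * YA - 3, 5 * YB - 3, 5 * YAB - 3)
        assert s1 == pytest.approx(s0, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedResultError):
            total_effects(np.ones(10), np.ones(10), np.zeros(10))

    @staticmethod
    def _saltelli_eval(fn, d, n_s, seed):
        rng = np.random.default_rng(seed)
        A, B = rng.random((n_s, d)), rng.random((n_s, d))
        YA, YB = fn(A), fn(B)
        out = []
        for i in range(d):
            M = A.copy()
            M[:, i] = B[:, i]
            out.append(total_effects(YA, YB, fn(M)))
        return np.array(out)

    def test_additive_linear_model(self):
        # closed form: S_T,i = a_i^2 / sum(a_k^2) for iid uniform inputs
        a = np.array([3.0, 1.0, 0.5, 0.0])
        fn = lambda X: X @ a
        st = self._saltelli_eval(fn, 4, 4096, seed=11)
        expected = a ** 2 / (a ** 2).sum()
        np.testing.assert_allclose(st, expected, atol=0.03)

    def test_single_parameter_function(self):
        fn = lambda X: np.sin(2 * np.pi * X[:, 2])
        st = self._saltelli_eval(fn, 4, 4096, seed=12)
        assert st[2] == pytest.approx(1.0, abs=0.05)
        assert max(st[0], st[1], st[3]) < 0.02


class TestBootstrap:
    def test_null_effect_gives_degenerate_interval(self):
        rng = np.random.default_rng(4)
        YA, YB = rng.random(60), rng.random(60)
        lo, hi = bootstrap_ci(YA, YB, YA.copy(), n_boot=200, seed=1)
        assert (lo, hi) == (0.0, 0.0)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(5)
        YA, YB, YAB = rng.random(60), rng.random(60), rng.random(60)
        assert bootstrap_ci(YA, YB, YAB, seed=7) == bootstrap_ci(YA, YB, YAB, seed=7)
        assert bootstrap_ci(YA, YB, YAB, seed=7) != bootstrap_ci(YA, YB, YAB, seed=8)

    def test_interval_contains_point_estimate(self):
        # coverage experiment on the additive linear model
        a = np.array([2.0, 1.0, 0.3])
        hits = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            A, B = rng.random((128, 3)), rng.random((128, 3))
            M = A.copy()
            M[:, 0] = B[:, 0]
            YA, YB, YAB = A @ a, B @ a, M @ a
            est = total_effects(YA, YB, YAB)
            lo, hi = bootstrap_ci(YA, YB, YAB, n_boot=300, seed=rep)
            hits += lo <= est <= hi
        assert hits / reps >= 0.95


class TestCampaign:
    def test_degenerate_design_flags_only_varying_parameter(self, small_scenario):
        """If only rho0 differs between A and B, rho0 is the only parameter
        with nonzero total effect."""
        space = table1_space("dox_cyc")
        fixed = space.midpoints()
        n_s = 6
        rng = np.random.default_rng(8)
        A = np.tile(fixed, (n_s, 1))
        B = A.copy()
        i_rho = PARAM_ORDER.index("rho0")
        A[:, i_rho] = 10 ** rng.uniform(-3, -1, n_s)
        B[:, i_rho] = 10 ** rng.uniform(-3, -1, n_s)
        design = saltelli_design(A, B)
        reg = standard_regimen("dox_cyc")
        rows = design.design_rows()
        res = simulate_batch(small_scenario, rows, reg)
        NT = res.NT[:, -1]
        YA, YB = NT[:n_s], NT[n_s:2 * n_s]
        st = [total_effects(YA, YB, NT[(2 + i) * n_s:(3 + i) * n_s])
              for i in range(15)]
        assert st[i_rho] > EPS_S
        assert max(v for i, v in enumerate(st) if i != i_rho) < 1e-10

    def test_run_sa_reproducible_and_resumable(self, small_scenario, tmp_path):
        kw = dict(n_s=4, seed=9, n_boot=50)
        r1 = run_sa(small_scenario, "dox_cyc", **kw)
        r2 = run_sa(small_scenario, "dox_cyc", **kw)
        np.testing.assert_array_equal(r1.ST, r2.ST)
        np.testing.assert_array_equal(r1.ci_lo, r2.ci_lo)
        # checkpointed run: first pass writes chunks, second pass reuses them
        ck = tmp_path / "ck"
        r3 = run_sa(small_scenario, "dox_cyc", checkpoint_dir=ck, **kw)
        assert any(ck.iterdir())
        r4 = run_sa(small_scenario, "dox_cyc", checkpoint_dir=ck, **kw)
        np.testing.assert_array_equal(r3.ST, r1.ST)
        np.testing.assert_array_equal(r4.ST, r1.ST)
        np.testing.assert_array_equal(r4.final_A, r1.final_A)

    def test_reduced_equals_original_when_nothing_fixed(self, small_scenario):
        rows = lhs(table1_space("dox_cyc"), 6, seed=13)
        report = reduced_model_comparison(
            small_scenario, "dox_cyc", np.ones(15, bool), rows)
        corr = report.correlations()
        for v in corr.values():
            assert v == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(report.VT_orig, report.VT_red)

    def test_fixing_parameters_changes_rows_only_where_masked(self, small_scenario):
        rows = lhs(table1_space("dox_cyc"), 4, seed=14)
        mask = np.zeros(15, bool)
        mask[[PARAM_ORDER.index("rho0"), PARAM_ORDER.index("E1n"),
              PARAM_ORDER.index("dm1")]] = True
        report = reduced_model_comparison(small_scenario, "dox_cyc", mask, rows)
        mids = table1_space("dox_cyc").midpoints()
        np.testing.assert_array_equal(report.fixed_values, mids)
        assert report.MRD_orig.shape == (4,)

    def test_empty_influential_set_rejected(self, small_scenario):
        with pytest.raises(ValueError):
            reduced_model_comparison(small_scenario, "dox_cyc",
                                     np.zeros(15, bool), np.zeros((2, 15)))
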