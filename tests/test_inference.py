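"""Permutation engines, effect sizes, RM-ANOVA and mixed-model comparisons."""

from itertools import permutations, product

import numpy as np
import pandas as pd
import pytest

from seqrsa.exceptions import DegeneratePredictorError, DesignValidationError
from seqrsa.inference import (
    cohens_d_hedges,
    deviation_code,
    fit_mixed_and_lrt,
    group_signflip_test,
    hedges_j,
    permutation_rm_anova,
    permutation_z,
)


def _brute_force_perm_p(y, x, t_obs):
    """Independent oracle: right-tail p over all n! shuffles of y."""
    count = total = 0
    X = np.column_stack([np.ones(len(x)), x])
    for perm in permutations(range(len(y))):
        yp = y[list(perm)]
        beta, res, *_ = np.linalg.lstsq(X, yp, rcond=None)
        resid = yp - X @ beta
        s2 = (resid ** 2).sum() / (len(y) - 2)
        invxtx = np.linalg.inv(X.T @ X)
        t = beta[1] / np.sqrt(s2 * invxtx[1, 1])
        count += t >= t_obs
        total += 1
    return count / total


class TestPermutationZ:
    def test_matches_exhaustive_enumeration(self, rng):
        y = rng.normal(size=6)
        x = rng.normal(size=6)
        X = pd.DataFrame({"x": x})
        res = permutation_z(y, X, n_perm=10_000, seed=0)
        oracle = _brute_force_perm_p(y, x, res.tvalues["x"])
        assert res.pvalues_right["x"] == pytest.approx(oracle, abs=0.02)
        exact = permutation_z(y, X, exhaustive=True)
        assert exact.pvalues_right["x"] == pytest.approx(oracle, abs=1e-12)

    def test_perfect_association_cap(self):
        x = np.arange(8.0)
        res = permutation_z(2 * x + 1, pd.DataFrame({"x": x}), n_perm=100, seed=3)
        assert res.pvalues_right["x"] == pytest.approx(1 / 101)
        from scipy.stats import norm

        assert res.zvalues["x"] == pytest.approx(norm.isf(1 / 101))
        assert res.zvalues["x"] == pytest.approx(2.33, abs=0.01)

    def test_strong_negative_effect_negative_bounded_z(self):
        x = np.arange(8.0)
        res = permutation_z(-2 * x, pd.DataFrame({"x": x}), n_perm=100, seed=3)
        assert res.zvalues["x"] == pytest.approx(-2.33, abs=0.01)
        assert np.isfinite(res.zvalues["x"])

    def test_z_monotone_in_observed_t(self, rng):
        # stronger association -> larger Z for the same permutation stream
        x = rng.normal(size=30)
        noise = rng.normal(size=30)
        zs = []
        for effect in (0.0, 0.5, 2.0):
            res = permutation_z(effect * x + noise, pd.DataFrame({"x": x}),
                                n_perm=500, seed=42)
            zs.append(res.zvalues["x"])
        assert zs == sorted(zs)

    def test_constant_outcome_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            permutation_z(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}), n_perm=100)

    def test_rank_deficient_rejected(self, rng):
        X = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(DegeneratePredictorError):
            permutation_z(rng.normal(size=10), X, n_perm=100)

    def test_low_n_perm_warns(self, rng):
        with pytest.warns(UserWarning, match="n_perm"):
            res = permutation_z(rng.normal(size=8),
                                pd.DataFrame({"x": rng.normal(size=8)}),
                                n_perm=50, seed=0)
        assert "warning" in res.meta


class TestGroupSignflip:
    def test_exhaustive_matches_monte_carlo(self, rng):
        x = rng.normal(0.8, 1.0, size=5)
        exact = group_signflip_test(x, exhaustive=True)
        mc = group_signflip_test(x, n_flips=20_000, seed=1)
        assert mc.p == pytest.approx(exact.p, abs=0.01)
        # n = 5: p has resolution 1/32 under full enumeration
        assert exact.p * 32 == pytest.approx(round(exact.p * 32))

    def test_all_zero_values(self):
        res = group_signflip_test(np.zeros(6), n_flips=100, seed=0)
        assert res.p == 1.0
        assert res.statistic == 0.0

    def test_negation_symmetry(self, rng):
        x = rng.normal(0.4, 1.0, size=10)
        p1 = group_signflip_test(x, n_flips=2000, seed=7).p
        p2 = group_signflip_test(-x, n_flips=2000, seed=7).p
        assert p1 == p2

    def test_paired_equals_difference_test(self, rng):
        a = rng.normal(1.0, 1.0, 12)
        b = rng.normal(0.0, 1.0, 12)
        paired = group_signflip_test(a, n_flips=3000, seed=9, paired_with=b)
        diff = group_signflip_test(a - b, n_flips=3000, seed=9)
        assert paired.p == diff.p
        assert paired.statistic == pytest.approx(diff.statistic)

    def test_ci_contains_point_estimate(self, rng):
        x = rng.normal(0.6, 1.0, 15)
        res = group_signflip_test(x, n_flips=500, seed=2)
        es = res.effect_size
        assert es["ci_low"] <= es["d"] <= es["ci_high"]


class TestEffectSizes:
    def test_hedges_correction_closed_form(self):
        # J(2) = 1 - 3/7 = 4/7; uncorrected d of (0,1,2) is exactly 1
        assert hedges_j(2) == pytest.approx(4 / 7)
        res = cohens_d_hedges(np.array([0.0, 1.0, 2.0]))
        assert res["d"] == pytest.approx(4 / 7)
        assert res["d"] == pytest.approx(0.571, abs=5e-4)

    def test_symmetric_values_give_zero_d(self):
        res = cohens_d_hedges(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert res["d"] == 0.0
        assert res["ci_low"] == pytest.approx(-res["ci_high"], abs=1e-6)

    def test_scale_invariance(self, rng):
        x = rng.normal(1.0, 2.0, 20)
        assert cohens_d_hedges(2 * x)["d"] == pytest.approx(cohens_d_hedges(x)["d"])

    def test_zero_sd_flag(self):
        res = cohens_d_hedges(np.full(5, 3.0))
        assert res["infinite"]


class TestPermutationRmAnova:
    @staticmethod
    def _long(cells):
        rows = []
        for s in range(cells.shape[0]):
            for i, a in enumerate(("a1", "a2")):
                for j, b in enumerate(("b1", "b2")):
                    rows.append({"subject": s, "A": a, "B": b, "y": cells[s, i, j]})
        return pd.DataFrame(rows)

    def test_all_equal_cells(self):
        data = self._long(np.full((6, 2, 2), 2.5))
        res = permutation_rm_anova(data, "y", ("A", "B"), n_perm=200, seed=0)
        for r in res.values():
            assert r.statistic == 0.0
            assert r.p == 1.0

    def test_f_matches_pingouin_on_toy(self, rng):
        pg = pytest.importorskip("pingouin")
        cells = rng.normal(size=(6, 2, 2)) + np.array([[0.0, 0.4], [0.1, 1.2]])
        data = self._long(cells)
        res = permutation_rm_anova(data, "y", ("A", "B"), n_perm=200, seed=0)
        table = pg.rm_anova(data=data, dv="y", within=["A", "B"],
                            subject="subject", detailed=True)
        for name, key in (("A", "A"), ("B", "B"), ("A * B", "A:B")):
            f_pg = float(table.loc[table.Source == name, "F"].iloc[0])
            assert res[key].statistic == pytest.approx(f_pg, rel=1e-8)

    def test_planted_interaction_detected_and_mains_null(self, rng):
        hits_int = hits_a = 0
        n_runs = 40
        for r in range(n_runs):
            g = np.random.default_rng(r)
            cells = g.normal(0, 1.0, size=(28, 2, 2))
            cells[:, 0, 0] += 0.5
            cells[:, 1, 1] += 0.5
            cells[:, 0, 1] -= 0.5
            cells[:, 1, 0] -= 0.5
            res = permutation_rm_anova(self._long(cells), "y", ("A", "B"),
                                       n_perm=300, seed=r)
            hits_int += res["A:B"].p < 0.05
            hits_a += res["A"].p < 0.05
        assert hits_int >= int(0.9 * n_runs)
        assert hits_a <= int(0.2 * n_runs)

    def test_subject_constant_shift_invariance(self, rng):
        cells = rng.normal(size=(8, 2, 2))
        shifted = cells.copy()
        shifted[3] += 7.5
        r1 = permutation_rm_anova(self._long(cells), "y", ("A", "B"), n_perm=200, seed=5)
        r2 = permutation_rm_anova(self._long(shifted), "y", ("A", "B"), n_perm=200, seed=5)
        for k in ("A", "B", "A:B"):
            assert r1[k].statistic == pytest.approx(r2[k].statistic)

    def test_missing_cell_rejected(self, rng):
        data = self._long(rng.normal(size=(5, 2, 2))).iloc[:-1]
        with pytest.raises(DesignValidationError):
            permutation_rm_anova(data, "y", ("A", "B"), n_perm=100, seed=0)


class TestMixedModels:
    @staticmethod
    def _simulate(rng, slope=0.3, n_subj=28, n_obs=40, icept_sd=0.2, noise=0.5):
        rows = []
        for s in range(n_subj):
            x = rng.normal(size=n_obs)
            icept = rng.normal(0, icept_sd)
            y = icept + slope * x + rng.normal(0, noise, n_obs)
            rows.append(pd.DataFrame({"subject": s, "x": x, "y": y}))
        return pd.concat(rows, ignore_index=True)

    def test_focal_absent_raises(self, rng):
        data = self._simulate(rng)
        with pytest.raises(DesignValidationError):
            fit_mixed_and_lrt(data, "y ~ x", focal="z")

    def test_slope_recovery_and_lrt_power(self):
        detected = 0
        slopes = []
        n_runs = 15
        for r in range(n_runs):
            data = self._simulate(np.random.default_rng(r))
            res = fit_mixed_and_lrt(data, "y ~ x", focal="x",
                                    re_ladder=("1 + x", "0 + x"))
            slopes.append(res.fe_params["x"])
            detected += res.p < 0.05
            assert res.chi2 >= 0.0
        assert detected >= int(0.9 * n_runs)
        assert np.mean(slopes) == pytest.approx(0.3, abs=0.1)

    def test_null_slope_chi2_small(self):
        data = self._simulate(np.random.default_rng(99), slope=0.0, n_subj=10)
        res = fit_mixed_and_lrt(data, "y ~ x", focal="x", re_ladder=("0 + x",))
        assert res.chi2 >= 0.0
        assert res.p > 0.001

    def test_ladder_must_keep_focal_slope(self, rng):
        data = self._simulate(rng, n_subj=6)
        with pytest.raises(DesignValidationError, match="focal"):
            fit_mixed_and_lrt(data, "y ~ x", focal="x", re_ladder=("1",))


def test_deviation_coding_two_levels():
    coded = deviation_code(pd.Series(["same", "diff", "same"]), levels=("same", "diff"))
    np.testing.assert_allclose(coded, [0.5, -0.5, 0.5])
    with pytest.raises(DesignValidationError):
        deviation_code(pd.Series([1, 2, 3]))
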