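import numpy as np
import pytest
from scipy.stats import rankdata

from clustrank import (
    ContrastMatrix,
    DegenerateCovarianceError,
    anova_f2,
    anova_test,
    build_design,
    contrast,
    estimate_effects,
    estimate_sigma,
    global_test_H0F,
    make_scheme,
    wald_test,
)
from clustrank.effects import EffectFit
from clustrank.variance import CovarianceFit
from conftest import random_design


def brunner_munzel_oracle(x, y):
    """Direct textbook Brunner-Munzel statistic and Welch-type df."""
    nx, ny = len(x), len(y)
    R = rankdata(np.concatenate([x, y]))
    Rx, Ry = R[:nx], R[nx:]
    Rix, Riy = rankdata(x), rankdata(y)
    phat = (Ry.mean() - (ny + 1) / 2) / nx
    Sx2 = np.sum((Rx - Rix - Rx.mean() + (nx + 1) / 2) ** 2) / (nx - 1)
    Sy2 = np.sum((Ry - Riy - Ry.mean() + (ny + 1) / 2) ** 2) / (ny - 1)
    sx2, sy2 = Sx2 / ny**2, Sy2 / nx**2
    T = (phat - 0.5) / np.sqrt(sx2 / nx + sy2 / ny)
    df = (sx2 / nx + sy2 / ny) ** 2 / (
        (sx2 / nx) ** 2 / (nx - 1) + (sy2 / ny) ** 2 / (ny - 1)
    )
    return T, df


def _fit_all(des, preset="unweighted"):
    sch = make_scheme(des, preset)
    fit = estimate_effects(des, sch)
    cov = estimate_sigma(des, sch, fit)
    return sch, fit, cov


class TestWald:
    def test_hand_arithmetic_oracle(self):
        # p_hat=(0.6,0.4), Sigma=I, centering contrast, g=20 -> Q = 20*0.02 = 0.4
        fit = EffectFit(np.array([0.6, 0.4]), None, None, None)
        cov = CovarianceFit(np.eye(2), None, None, None, None, g_n=20.0)
        res = wald_test(fit, cov, contrast("centering", 2))
        assert res.statistic == pytest.approx(0.4, abs=1e-12)
        assert res.rank == 1

    def test_identical_groups_statistic_zero(self):
        rows = [(g, f"c{j}", float(j)) for g in "ab" for j in range(4)]
        des = build_design(rows)
        sch, fit, cov = _fit_all(des)
        res = wald_test(fit, cov, contrast("centering", 2))
        assert res.statistic == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)

    def test_constant_data_degenerate(self):
        rows = [(g, f"c{j}", 1.0) for g in "ab" for j in range(3)]
        des = build_design(rows)
        sch, fit, cov = _fit_all(des)
        with pytest.raises(DegenerateCovarianceError):
            wald_test(fit, cov, contrast("centering", 2))

    def test_invariant_to_row_scaling(self, rng):
        des = random_design(rng, d=3)
        sch, fit, cov = _fit_all(des)
        C = contrast("tukey", 3)
        C2 = ContrastMatrix(2.5 * C.entries)
        q1 = wald_test(fit, cov, C).statistic
        q2 = wald_test(fit, cov, C2).statistic
        assert q1 == pytest.approx(q2, rel=1e-10)


class TestAnova:
    def test_reduces_to_brunner_munzel(self, rng):
        # d=2, one observation per cluster, weighted preset: Q = T_BM^2, f2 = df_BM
        for _ in range(25):
            x = rng.normal(0, 1, int(rng.integers(8, 15)))
            y = rng.normal(0.3, 2, int(rng.integers(8, 15)))
            rows = [("a", f"a{j}", v) for j, v in enumerate(x)] + [
                ("b", f"b{j}", v) for j, v in enumerate(y)
            ]
            des = build_design(rows)
            sch, fit, cov = _fit_all(des, "weighted")
            res = anova_test(des, sch, fit, cov, contrast("centering", 2), approx="F")
            T, df = brunner_munzel_oracle(x, y)
            assert res.statistic == pytest.approx(T**2, abs=1e-10)
            assert res.df[1] == pytest.approx(df, abs=1e-10)
            assert res.df[0] == pytest.approx(1.0, abs=1e-10)

    def test_constant_data_degenerate(self):
        rows = [(g, f"c{j}", 1.0) for g in "ab" for j in range(3)]
        des = build_design(rows)
        sch, fit, cov = _fit_all(des)
        with pytest.raises(DegenerateCovarianceError):
            anova_test(des, sch, fit, cov, contrast("centering", 2))

    def test_depends_only_on_contrast_row_space(self, rng):
        des = random_design(rng, d=4)
        sch, fit, cov = _fit_all(des)
        C = contrast("tukey", 4)
        perm = np.random.default_rng(0).permutation(C.q)
        C2 = ContrastMatrix(3.0 * C.entries[perm])
        r1 = anova_test(des, sch, fit, cov, C)
        r2 = anova_test(des, sch, fit, cov, C2)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-10)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-8)

    def test_monotone_transform_invariance(self, rng):
        des = random_design(rng, d=3, tie_prob=0.0)
        sch, fit, cov = _fit_all(des)
        C = contrast("centering", 3)
        r1 = anova_test(des, sch, fit, cov, C)
        des2 = des.transform(np.exp)
        sch2, fit2, cov2 = _fit_all(des2)
        r2 = anova_test(des2, sch2, fit2, cov2, C)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.df == pytest.approx(r2.df, abs=1e-10)

    def test_f2_grows_with_n(self, rng):
        for n_i in (8, 32, 128):
            rows = [
                (g, f"c{j}", float(rng.normal()))
                for g in "ab"
                for j in range(n_i)
                for _ in range(2)
            ]
            des = build_design(rows)
            sch = make_scheme(des, "unweighted")
            assert anova_f2(des, sch) >= des.n / 4

    def test_chi2_variant_shares_statistic(self, rng):
        des = random_design(rng, d=3, max_clusters=6)
        sch, fit, cov = _fit_all(des)
        C = contrast("centering", 3)
        rF = anova_test(des, sch, fit, cov, C, approx="F")
        rc = anova_test(des, sch, fit, cov, C, approx="chi2")
        assert rc.statistic == pytest.approx(rF.statistic, abs=1e-14)
        assert rc.df[1] == np.inf and 0.0 <= rc.p_value <= 1.0


class TestH0F:
    def test_no_cluster_weighted_matches_direct_variance(self, rng):
        rows = [(g, f"c{j}", float(rng.integers(0, 5))) for g in "ab" for j in range(8)]
        des = build_design(rows)
        sch = make_scheme(des, "weighted")
        from clustrank import estimate_sigma_H0F, edf_value

        s2 = estimate_sigma_H0F(des, sch)
        for i in range(2):
            x = np.concatenate(des.clusters[i])
            n_i = len(x)
            psi = 1 / n_i
            kappa = 1 - 2 * psi + n_i * psi**2
            Y = edf_value(x, np.full(n_i, psi), x)
            expect = np.sum((Y - Y.mean()) ** 2) * psi**2 / kappa
            assert s2[i] == pytest.approx(expect, abs=1e-14)

    def test_constant_data_degenerate(self):
        rows = [(g, f"c{j}", 1.0) for g in "ab" for j in range(3)]
        des = build_design(rows)
        with pytest.raises(DegenerateCovarianceError):
            global_test_H0F(des, make_scheme(des, "unweighted"), contrast("centering", 2))

    def test_level_under_identical_distributions(self):
        # rejection rate at alpha=0.1 stays near nominal for iid groups
        rng = np.random.default_rng(5)
        rej_w = rej_a = 0
        reps = 400
        for _ in range(reps):
            rows = [
                (g, f"c{j}", float(rng.normal()))
                for g in "abc"
                for j in range(12)
                for _ in range(2)
            ]
            des = build_design(rows)
            sch = make_scheme(des, "unweighted")
            C = contrast("centering", 3)
            rej_a += global_test_H0F(des, sch, C, kind="anova").p_value <= 0.1
            rej_w += global_test_H0F(des, sch, C, kind="wald").p_value <= 0.1
        assert 0.04 <= rej_a / reps <= 0.18
        assert 0.04 <= rej_w / reps <= 0.25  # wald runs liberal
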