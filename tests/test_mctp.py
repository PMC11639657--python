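import numpy as np
import pytest
from scipy.stats import norm, t as tdist

from clustrank import (
    ContrastMatrix,
    DesignError,
    build_design,
    contrast,
    estimate_effects,
    estimate_sigma,
    fisher_sci,
    make_scheme,
    mctp,
    satterthwaite_df,
    zeta,
    zeta_inv,
)
from conftest import random_design
from test_global import brunner_munzel_oracle


def _prep(des, preset="unweighted"):
    sch = make_scheme(des, preset)
    fit = estimate_effects(des, sch)
    cov = estimate_sigma(des, sch, fit)
    return sch, fit, cov


class TestMctp:
    def test_single_contrast_normal_equals_z_test(self, rng):
        des = random_design(rng, d=2, max_clusters=8)
        sch, fit, cov = _prep(des)
        C = ContrastMatrix(np.array([[-1.0, 1.0]]))
        res = mctp(des, sch, C, approx="normal", transform="raw")
        # closed-form two-sided z-test on the same standardized statistic
        T = np.sqrt(sch.g_n / (C.entries @ cov.sigma_hat @ C.entries.T)[0, 0]) * (
            fit.p_hat[1] - fit.p_hat[0]
        )
        assert res.T[0] == pytest.approx(T, abs=1e-12)
        assert res.crit == pytest.approx(norm.ppf(0.975), abs=1e-9)
        assert res.p_adjusted[0] == pytest.approx(2 * norm.sf(abs(T)), abs=1e-9)
        half = norm.ppf(0.975) * res.se[0]
        assert res.sci_lower[0] == pytest.approx(res.delta_hat[0] - half, abs=1e-9)

    def test_symmetric_data_null_results(self):
        rows = [(g, f"c{j}", v) for g in "ab" for j, v in enumerate([1.0, 2.0, 3.0])]
        des = build_design(rows)
        sch, fit, cov = _prep(des)
        res = mctp(des, sch, contrast("centering", 2))
        assert np.allclose(res.delta_hat, 0.0, atol=1e-15)
        assert np.allclose(res.T, 0.0, atol=1e-12)
        assert np.allclose(res.p_adjusted, 1.0, atol=1e-9)
        assert np.allclose(res.sci_lower, -res.sci_upper, atol=1e-9)

    def test_marginal_t_matches_brunner_munzel(self, rng):
        # d=2, m=1, weighted preset, pairwise contrast: T and nu equal the BM test
        for _ in range(10):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0.4, 2, 13)
            rows = [("a", f"a{j}", v) for j, v in enumerate(x)] + [
                ("b", f"b{j}", v) for j, v in enumerate(y)
            ]
            des = build_design(rows)
            sch, fit, cov = _prep(des, "weighted")
            res = mctp(
                des, sch, ContrastMatrix(np.array([[-1.0, 1.0]])),
                approx="t", transform="raw", detail="global",
            )
            T, df = brunner_munzel_oracle(x, y)
            assert res.T[0] == pytest.approx(T, abs=1e-10)
            assert res.nu_hat == pytest.approx(df, abs=1e-10)

    def test_adjusted_p_not_below_marginal(self, rng):
        for _ in range(10):
            des = random_design(rng, d=3, max_clusters=6)
            sch, fit, cov = _prep(des)
            res = mctp(des, sch, contrast("tukey", 3), detail="padj")
            marginal = 2 * tdist.sf(np.abs(res.T), res.nu_hat)
            assert np.all(res.p_adjusted >= marginal - 2e-3)

    def test_consonance_global_equals_min_adjusted(self, rng):
        for _ in range(5):
            des = random_design(rng, d=3, max_clusters=7)
            sch, fit, cov = _prep(des)
            res = mctp(des, sch, contrast("tukey", 3))
            assert res.p_global == pytest.approx(np.min(res.p_adjusted), abs=1e-9)
            # max-test rejection agrees with per-contrast decisions
            assert (res.p_global <= res.alpha) == bool(np.any(res.reject()))

    def test_raw_and_fisher_decisions_agree(self, rng):
        mismatch = total = 0
        for _ in range(60):
            des = random_design(rng, d=3, max_clusters=6, tie_prob=0.3)
            sch, fit, cov = _prep(des)
            try:
                r_raw = mctp(des, sch, contrast("tukey", 3), transform="raw",
                             detail="padj", tol=2e-3)
                r_fis = mctp(des, sch, contrast("tukey", 3), transform="fisher",
                             detail="padj", tol=2e-3)
            except Exception:
                continue
            keep = np.abs(r_raw.delta_hat) <= 0.3
            total += keep.sum()
            mismatch += np.sum(
                (r_raw.p_adjusted[keep] <= 0.05) != (r_fis.p_adjusted[keep] <= 0.05)
            )
        assert total > 100
        assert mismatch / total <= 0.02

    def test_alpha_validation(self, rng):
        des = random_design(rng, d=2)
        sch, fit, cov = _prep(des)
        with pytest.raises(DesignError):
            mctp(des, sch, contrast("centering", 2), alpha=1.5)

    def test_fisher_requires_normed_contrast(self, rng):
        des = random_design(rng, d=2)
        sch, _, _ = _prep(des)
        C = ContrastMatrix(np.array([[-2.0, 2.0]]))
        with pytest.raises(DesignError, match="normed"):
            mctp(des, sch, C, transform="fisher")

    def test_seed_determinism(self, rng):
        des = random_design(rng, d=3)
        sch, fit, cov = _prep(des)
        r1 = mctp(des, sch, contrast("tukey", 3), seed=42)
        r2 = mctp(des, sch, contrast("tukey", 3), seed=42)
        assert r1.crit == r2.crit
        assert np.array_equal(r1.p_adjusted, r2.p_adjusted)
        assert np.array_equal(r1.sci_lower, r2.sci_lower)


class TestSatterthwaite:
    def test_homogeneous_groups_closed_form(self, rng):
        # equal v_li^2 across d groups of n0 clusters -> nu_l = d (n0 - 1)
        d, n0 = 3, 6
        rows = [(f"g{i}", f"c{j}", 0.0) for i in range(d) for j in range(n0)]
        des = build_design(rows)
        sch = make_scheme(des, "unweighted")
        rng2 = np.random.default_rng(1)
        base = rng2.normal(size=n0)
        A = np.zeros((d, d * n0))
        A[0] = np.tile(base, d)  # identical cluster spread in every group
        C = ContrastMatrix(np.array([[1.0, -1.0, 0.0]]))
        nu, nu_l = satterthwaite_df(des, sch, A, C)
        assert nu == pytest.approx(d * (n0 - 1), rel=1e-12)

    def test_floor_at_one(self, rng):
        for _ in range(10):
            des = random_design(rng)
            sch, fit, cov = _prep(des)
            nu, _ = satterthwaite_df(des, sch, cov.A_hats, contrast("centering", des.d))
            assert nu >= 1.0

    def test_degenerate_flags_infinite(self):
        rows = [(g, f"c{j}", 1.0) for g in "ab" for j in range(3)]
        des = build_design(rows)
        sch = make_scheme(des, "unweighted")
        A = np.zeros((2, 6))
        nu, nu_l = satterthwaite_df(des, sch, A, contrast("centering", 2))
        assert nu == np.inf


class TestFisherSci:
    def test_round_trip(self):
        x = np.linspace(-0.9, 0.9, 19)
        assert np.allclose(zeta_inv(zeta(x)), x, atol=1e-12)

    def test_zero_estimate_symmetric_tanh_interval(self):
        lo, hi, T = fisher_sci(np.array([0.0]), np.array([[0.8]]), g_n=25.0, crit=2.0)
        w = 2.0 * np.sqrt(0.8 / 25.0)
        assert lo[0] == pytest.approx(np.tanh(-w), abs=1e-12)
        assert hi[0] == pytest.approx(np.tanh(w), abs=1e-12)
        assert T[0] == 0.0

    def test_range_preserving_near_boundary(self):
        lo, hi, _ = fisher_sci(np.array([0.95]), np.array([[1e-4]]), g_n=50.0, crit=3.0)
        assert -1.0 < lo[0] < hi[0] < 1.0

    def test_boundary_clipped_with_warning(self):
        # at the clipped boundary the back-transform saturates in floats;
        # the contract is the warning plus a finite, ordered interval
        with pytest.warns(UserWarning, match="clipping"):
            lo, hi, _ = fisher_sci(np.array([1.0]), np.array([[0.1]]), g_n=10.0, crit=2.0)
        assert np.isfinite(lo[0]) and np.isfinite(hi[0])
        assert lo[0] < hi[0] <= 1.0
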