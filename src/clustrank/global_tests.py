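"""Global Wald-type and ANOVA-type tests of H0: Cp = 0 and H0F: CF = 0.

The Wald statistic uses a Moore-Penrose inverse of the projected covariance
and a chi-square reference with its estimated rank; it is known to be liberal
in small samples.  The ANOVA-type statistic normalizes by the trace of the
projected covariance and uses an F(f1, f2) reference where f1 is a
Box-type trace ratio and f2 a rank-based Satterthwaite-style denominator
degree of freedom; this is the recommended global test for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import ClusteredDesign, WeightScheme, ContrastMatrix, DesignError
from .effects import EffectFit, estimate_effects, ranks
from .variance import CovarianceFit, estimate_sigma, estimate_sigma_H0F

__all__ = [
    "GlobalTestResult",
    "DegenerateCovarianceError",
    "wald_test",
    "anova_test",
    "anova_f2",
    "global_test_H0F",
]

_PINV_RTOL = 1e-8  # relative singular-value cutoff for pseudo-inverse / rank


class DegenerateCovarianceError(ValueError):
    """Covariance estimate carries no information (e.g. constant data)."""


@dataclass(frozen=True)
class GlobalTestResult:
    statistic: float
    df: tuple  # (df1, df2); df2 = inf for chi-square approximations
    p_value: float
    method: str
    rank: int | None = None


def _project(C: ContrastMatrix) -> np.ndarray:
    """Row-space projection M = C'(CC')^- C (depends on the row space only)."""
    Cm = C.entries
    return Cm.T @ np.linalg.pinv(Cm @ Cm.T, rcond=_PINV_RTOL) @ Cm


def wald_test(fit: EffectFit, cov: CovarianceFit, C: ContrastMatrix) -> GlobalTestResult:
    """Wald-type statistic Q = g_n p̂' C' (C Sigma_hat C')^+ C p̂, chi-square ref."""
    Cm = C.entries
    Mhat = Cm @ cov.sigma_hat @ Cm.T
    sv = np.linalg.svd(Mhat, compute_uv=False)
    rank = int(np.sum(sv > _PINV_RTOL * (sv[0] if len(sv) else 0.0)))
    if rank == 0:
        raise DegenerateCovarianceError("degenerate covariance: C Sigma C' has rank 0")
    v = Cm @ fit.p_hat
    Q = float(cov.g_n * v @ np.linalg.pinv(Mhat, rcond=_PINV_RTOL) @ v)
    p = float(stats.chi2.sf(Q, rank))
    return GlobalTestResult(Q, (float(rank), np.inf), p, "wald", rank=rank)


def anova_f2(design: ClusteredDesign, scheme: WeightScheme) -> float:
    """Denominator degrees of freedom f2 from global and internal ranks.

    S_i^2 aggregates the squared centered differences between global and
    group-internal (pseudo-)ranks with the scheme's within-cluster weights;
    f2 combines the S_i^2 Welch-style across groups (n = total clusters).
    """
    flat_R, flat_Rint = ranks(design, scheme)
    d = design.d
    n = design.n
    n_i = design.n_i
    M_i = design.M_i
    S2 = np.empty(d)
    # reconstruct flat indexing (same order as effects._Flat)
    obs_group = np.concatenate(
        [np.full(sum(len(v) for v in g), i) for i, g in enumerate(design.clusters)]
    )
    omega = np.concatenate(
        [np.asarray(w, float) for grp in scheme.omega for w in grp]
    )
    psi_obs = np.concatenate(
        [
            np.full(len(design.clusters[i][j]), scheme.psi[i][j])
            for i in range(d)
            for j in range(len(design.clusters[i]))
        ]
    )
    for i in range(d):
        sel = obs_group == i
        Rbar = float(np.sum(psi_obs[sel] * omega[sel] * flat_R[sel]))
        dev = flat_R[sel] - flat_Rint[sel] - Rbar + (M_i[i] + 1) / 2.0
        S2[i] = np.sum(omega[sel] * dev**2) / (n_i[i] - 1)
    a = S2 / (n - n_i)
    denom = float(np.sum(a**2 / (n_i - 1)))
    if denom <= 0.0:
        return np.inf
    return float(np.sum(a) ** 2 / denom)


def _anova_from_cov(
    design: ClusteredDesign,
    scheme: WeightScheme,
    p_hat: np.ndarray,
    sigma: np.ndarray,
    C: ContrastMatrix,
    approx: str,
    method: str,
) -> GlobalTestResult:
    MP = _project(C)
    tr = float(np.trace(MP @ sigma))
    if tr <= 0.0:
        raise DegenerateCovarianceError("degenerate covariance: tr(M Sigma) <= 0")
    Q = float(scheme.g_n * p_hat @ MP @ p_hat / tr)
    MS = MP @ sigma
    f1 = tr**2 / float(np.trace(MS @ MS))
    if approx == "F":
        f2 = anova_f2(design, scheme)
        p = float(stats.f.sf(Q, f1, f2)) if np.isfinite(f2) else float(
            stats.chi2.sf(Q * f1, f1)
        )
        return GlobalTestResult(Q, (f1, f2), p, method)
    elif approx == "chi2":
        p = float(stats.chi2.sf(Q * f1, f1))
        return GlobalTestResult(Q, (f1, np.inf), p, method + "_chi2")
    raise DesignError(f"unknown approximation {approx!r}")


def anova_test(
    design: ClusteredDesign,
    scheme: WeightScheme,
    fit: EffectFit,
    cov: CovarianceFit,
    C: ContrastMatrix,
    approx: str = "F",
) -> GlobalTestResult:
    """ANOVA-type statistic Q = g_n p̂' M p̂ / tr(M Sigma_hat), F(f1, f2) ref.

    With d = 2, one observation per cluster and the weighted preset this
    reproduces the Brunner-Munzel test (Q = T^2, f2 = its df).
    """
    return _anova_from_cov(design, scheme, fit.p_hat, cov.sigma_hat, C, approx, "anova_f")


def global_test_H0F(
    design: ClusteredDesign,
    scheme: WeightScheme,
    C: ContrastMatrix,
    kind: str = "anova",
    approx: str = "F",
) -> GlobalTestResult:
    """Wald- or ANOVA-type test of equal distribution functions H0F: CF = 0.

    Under H0F all relative effects equal 1/2 and the covariance of the
    groupwise mean placements is diagonal; the same quadratic forms are used
    with that diagonal estimate.
    """
    fit = estimate_effects(design, scheme)
    sigF = scheme.g_n * np.diag(estimate_sigma_H0F(design, scheme))
    if kind == "wald":
        Cm = C.entries
        Mhat = Cm @ sigF @ Cm.T
        sv = np.linalg.svd(Mhat, compute_uv=False)
        rank = int(np.sum(sv > _PINV_RTOL * (sv[0] if len(sv) else 0.0)))
        if rank == 0:
            raise DegenerateCovarianceError("degenerate covariance under H0F")
        v = Cm @ fit.p_hat
        Q = float(scheme.g_n * v @ np.linalg.pinv(Mhat, rcond=_PINV_RTOL) @ v)
        return GlobalTestResult(
            Q, (float(rank), np.inf), float(stats.chi2.sf(Q, rank)), "wald_H0F", rank=rank
        )
    elif kind == "anova":
        res = _anova_from_cov(design, scheme, fit.p_hat, sigF, C, approx, "anova_H0F")
        return res
    raise DesignError(f"unknown H0F test kind {kind!r}")
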