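"""Multiple contrast test procedures (MCTPs) with simultaneous confidence
intervals.

Each row c_l of the contrast matrix defines an individual hypothesis
H0(l): c_l'p = 0.  The vector of standardized contrast statistics is jointly
approximated by a multivariate normal (large samples) or central multivariate
t distribution (small samples, Satterthwaite-Welch degrees of freedom) with
the estimated correlation matrix R_hat, giving single-step familywise-exact
tests, adjusted p-values and compatible simultaneous confidence intervals.

Because contrast effects live in (-1, 1), the recommended interval scale is
the Fisher transform zeta(x) = artanh(x): the delta method gives the
variance on the transformed scale and back-transforming with tanh yields
range-preserving intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .design import ClusteredDesign, WeightScheme, ContrastMatrix, DesignError
from .effects import EffectFit, estimate_effects
from .variance import CovarianceFit, estimate_sigma, kappa_factors
from .global_tests import DegenerateCovarianceError
from .mvquant import rect_prob, equicoordinate_quantile, DEFAULT_SEED

__all__ = ["MCTPResult", "mctp", "satterthwaite_df", "fisher_sci", "zeta", "zeta_inv"]

_CLIP = 1.0 - 1e-12


def zeta(x):
    """Fisher transform 0.5*log((1+x)/(1-x)) = artanh(x)."""
    return np.arctanh(x)


def zeta_inv(y):
    """Inverse Fisher transform tanh(y), mapping into (-1, 1)."""
    return np.tanh(y)


@dataclass(frozen=True)
class MCTPResult:
    """Per-contrast estimates, statistics, simultaneous CIs and p-values."""

    labels: tuple
    delta_hat: np.ndarray  # c_l' p̂
    T: np.ndarray  # statistics on the scale actually tested
    se: np.ndarray  # sqrt(Upsilon_ll / g_n), raw scale
    R_hat: np.ndarray
    nu_hat: float  # inf for the normal approximation
    crit: float | None
    sci_lower: np.ndarray | None
    sci_upper: np.ndarray | None
    p_adjusted: np.ndarray | None
    global_statistic: float
    p_global: float
    transform: str
    approx: str
    alpha: float

    def reject(self) -> np.ndarray:
        """Per-contrast familywise rejection decisions at level alpha."""
        return np.abs(self.T) >= self.crit


def satterthwaite_df(
    design: ClusteredDesign,
    scheme: WeightScheme,
    A_hats: np.ndarray,
    C: ContrastMatrix,
):
    """Conservative multivariate-t degrees of freedom nu_hat = max(1, min_l nu_l).

    For each contrast, the variance of c_l' applied to the cluster vectors is
    decomposed into group components v_li^2 = sum_j psi_ij^2/kappa_ij
    (Lambda_lij - mean)^2 and combined Welch-style:
    nu_l = (sum_i v_li^2)^2 / sum_i v_li^4/(n_i - 1).

    Returns ``(nu_hat, nu_l)``; nu_hat is inf when every contrast is
    degenerate (all v_li^2 = 0, in which case t reduces to normal).
    """
    Lam = C.entries @ A_hats  # q x n_clusters
    q = Lam.shape[0]
    d = design.d
    n_i = design.n_i
    kap = kappa_factors(scheme)
    v2 = np.zeros((q, d))
    cl0 = 0
    for i in range(d):
        sl = slice(cl0, cl0 + int(n_i[i]))
        psi = np.asarray(scheme.psi[i], float)
        Lbar = Lam[:, sl] @ psi
        dev = Lam[:, sl] - Lbar[:, None]
        v2[:, i] = dev**2 @ (psi**2 / np.asarray(kap[i]))
        cl0 += int(n_i[i])
    num = v2.sum(axis=1) ** 2
    den = (v2**2 / (n_i - 1)[None, :]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nu_l = np.where(den > 0, num / den, np.inf)
    finite = nu_l[np.isfinite(nu_l)]
    if len(finite) == 0:
        return np.inf, nu_l
    return float(max(1.0, np.min(nu_l))), nu_l


def fisher_sci(delta_hat, Upsilon, g_n, crit):
    """Fisher-scale simultaneous intervals and statistics.

    Gamma = eta Upsilon eta' with eta = diag(1/(1 - delta_l^2)) is the delta
    method covariance of zeta(delta_hat); intervals are
    tanh(zeta(delta_hat) -/+ crit * sqrt(Gamma_ll / g_n)) and the returned
    statistics are T~_l = sqrt(g_n / Gamma_ll) * zeta(delta_hat_l).
    Estimates on the boundary are clipped to +/-(1 - 1e-12) with a warning.
    """
    delta_hat = np.asarray(delta_hat, float)
    if np.any(np.abs(delta_hat) >= 1.0):
        warnings.warn("contrast estimate on the boundary +/-1; clipping before artanh")
        delta_hat = np.clip(delta_hat, -_CLIP, _CLIP)
    eta = 1.0 / (1.0 - delta_hat**2)
    Gamma_ll = eta**2 * np.diag(np.atleast_2d(Upsilon))
    half = crit * np.sqrt(Gamma_ll / g_n) if crit is not None else None
    z = zeta(delta_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        T_tilde = np.where(Gamma_ll > 0, np.sqrt(g_n / Gamma_ll) * z, 0.0)
    if half is None:
        return None, None, T_tilde
    return zeta_inv(z - half), zeta_inv(z + half), T_tilde


def mctp(
    design: ClusteredDesign,
    scheme: WeightScheme,
    C: ContrastMatrix,
    alpha: float = 0.05,
    approx: str = "t",
    transform: str = "fisher",
    tol: float = 5e-4,
    seed: int = DEFAULT_SEED,
    fit: EffectFit | None = None,
    cov: CovarianceFit | None = None,
    detail: str = "full",
) -> MCTPResult:
    """Single-step multiple contrast test of the family H0(l): c_l'p = 0.

    ``approx="t"`` (default) uses a central multivariate t reference with the
    conservative Satterthwaite-Welch df; ``approx="normal"`` the multivariate
    normal.  ``transform="fisher"`` (default, recommended for small samples)
    tests and inverts on the variance-stabilized artanh scale, giving
    range-preserving intervals; ``transform="raw"`` works on the original
    contrast scale.  ``detail="global"`` skips critical value and SCIs and
    only computes the global max-test p-value (used by simulation loops).
    """
    if not 0.0 < alpha < 1.0:
        raise DesignError("alpha must be in (0, 1)")
    if transform not in ("raw", "fisher") or approx not in ("t", "normal"):
        raise DesignError("unknown transform/approx")
    if transform == "fisher" and not C.is_normed:
        raise DesignError("fisher transform requires a normed contrast (max |c_li| <= 1)")
    if fit is None:
        fit = estimate_effects(design, scheme)
    if cov is None:
        cov = estimate_sigma(design, scheme, fit)
    Cm = C.entries
    g_n = scheme.g_n
    Upsilon = Cm @ cov.sigma_hat @ Cm.T
    Ull = np.diag(Upsilon).copy()
    bad = np.nonzero(Ull <= 0)[0]
    if len(bad):
        raise DegenerateCovarianceError(
            f"zero variance for contrast {C.labels[bad[0]]!r}"
        )
    delta = Cm @ fit.p_hat
    T_raw = np.sqrt(g_n / Ull) * delta
    s = np.sqrt(Ull)
    R_hat = Upsilon / np.outer(s, s)
    np.fill_diagonal(R_hat, 1.0)

    if approx == "t":
        nu_hat, _ = satterthwaite_df(design, scheme, cov.A_hats, C)
    else:
        nu_hat = np.inf

    if transform == "fisher":
        _, _, T_used = fisher_sci(delta, Upsilon, g_n, None)
    else:
        T_used = T_raw

    tmax = float(np.max(np.abs(T_used)))
    p_global = float(1.0 - rect_prob(R_hat, nu_hat, tmax, tol=tol, seed=seed))

    if detail in ("global", "padj"):
        p_adj = None
        if detail == "padj":
            p_adj = np.array(
                [1.0 - rect_prob(R_hat, nu_hat, abs(t), tol=tol, seed=seed) for t in T_used]
            )
        return MCTPResult(
            labels=C.labels, delta_hat=delta, T=T_used, se=np.sqrt(Ull / g_n),
            R_hat=R_hat, nu_hat=nu_hat, crit=None, sci_lower=None, sci_upper=None,
            p_adjusted=p_adj, global_statistic=tmax, p_global=p_global,
            transform=transform, approx=approx, alpha=alpha,
        )

    crit = equicoordinate_quantile(R_hat, nu_hat, alpha, tol=tol, seed=seed)
    p_adj = np.array(
        [1.0 - rect_prob(R_hat, nu_hat, abs(t), tol=tol, seed=seed) for t in T_used]
    )
    if transform == "fisher":
        lo, hi, _ = fisher_sci(delta, Upsilon, g_n, crit)
    else:
        half = crit * np.sqrt(Ull / g_n)
        lo, hi = delta - half, delta + half
    return MCTPResult(
        labels=C.labels, delta_hat=delta, T=T_used, se=np.sqrt(Ull / g_n),
        R_hat=R_hat, nu_hat=nu_hat, crit=crit, sci_lower=lo, sci_upper=hi,
        p_adjusted=p_adj, global_statistic=tmax, p_global=p_global,
        transform=transform, approx=approx, alpha=alpha,
    )
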