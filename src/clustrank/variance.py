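"""Covariance estimation for the standardized effect vector sqrt(g_n)(p̂ - p).

The asymptotic representation writes sqrt(g_n)(p̂ - p) as a weighted sum of
independent per-cluster vectors A_ij built from cross-group placements
Y_ab^(c) = sum_k omega_abk F_c(X_abk).  Their empirical counterparts Â_ij give
the plug-in covariance estimator with a per-cluster small-sample bias
correction factor

    kappa_ij = 1 - 2 psi_ij + sum_j' psi_ij'^2  in (0, 1].

A diagonal variant under the hypothesis of equal distribution functions
(H0F) uses own-group placements only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ClusteredDesign, WeightScheme, DesignError
from .effects import EffectFit, _Flat, estimate_effects

__all__ = [
    "CovarianceFit",
    "compute_A_hats",
    "estimate_sigma",
    "estimate_sigma_H0F",
    "kappa_factors",
]


@dataclass(frozen=True)
class CovarianceFit:
    """Estimated covariance of sqrt(g_n)(p̂ - p) with its building blocks.

    ``A_hats[:, c]`` is the vector Â_ij of (global) cluster ``c``;
    ``kappa[c]`` the bias-correction factor of that cluster.
    """

    sigma_hat: np.ndarray
    A_hats: np.ndarray
    kappa: np.ndarray
    group_of_cluster: np.ndarray
    psi_cl: np.ndarray
    g_n: float


def kappa_factors(scheme: WeightScheme) -> tuple:
    """Per-cluster kappa_ij = 1 - 2 psi_ij + sum_j' psi_ij'^2, grouped."""
    return tuple(1.0 - 2.0 * np.asarray(ps) + np.sum(np.asarray(ps) ** 2) for ps in scheme.psi)


def _cluster_Y(flat: _Flat) -> np.ndarray:
    """Ŷ[c, cl] = sum_k omega_{cl,k} Fhat_{c,psi}(X_{cl,k}) for all groups c."""
    G = flat.group_edf_at(flat.values)  # d x M
    Y = np.zeros((flat.d, flat.n_cl))
    for c in range(flat.d):
        np.add.at(Y[c], flat.cluster_of_obs, flat.omega_obs * G[c])
    return Y


def compute_A_hats(design: ClusteredDesign, scheme: WeightScheme, fit: EffectFit | None = None) -> np.ndarray:
    """Empirical per-cluster vectors Â_ij, returned as a d x n matrix.

    Component h of Â_ij is ``sum_{s != i} theta_s Ŷ_ij^(s)`` when ``h = i``
    and ``- theta_i Ŷ_ij^(h)`` otherwise; only cross-group placements enter.
    """
    flat = _Flat(design, scheme)
    Y = _cluster_Y(flat)
    th = flat.theta
    A = -th[flat.group_of_cl][None, :] * Y  # h != i branch for every h
    for cl in range(flat.n_cl):
        i = flat.group_of_cl[cl]
        A[i, cl] = np.sum(np.delete(th * Y[:, cl], i))
    return A


def estimate_sigma(
    design: ClusteredDesign,
    scheme: WeightScheme,
    fit: EffectFit | None = None,
) -> CovarianceFit:
    """Bias-corrected covariance estimator

    ``Sigma_hat = g_n sum_i sum_j psi_ij^2 / kappa_ij (Â_ij - Ābar_i)(...)'``.

    Requires at least two clusters per group (kappa_ij = 0 when psi_ij = 1).
    """
    if np.any(design.n_i < 2):
        raise DesignError("variance requires >=2 clusters per group")
    flat = _Flat(design, scheme)
    A = compute_A_hats(design, scheme, fit)
    kap_by_group = kappa_factors(scheme)
    kappa = np.empty(flat.n_cl)
    sigma = np.zeros((flat.d, flat.d))
    cl0 = 0
    for i in range(flat.d):
        ni = design.n_i[i]
        sl = slice(cl0, cl0 + ni)
        psi = flat.psi_cl[sl]
        kap = np.asarray(kap_by_group[i])
        kappa[sl] = kap
        Abar = A[:, sl] @ psi
        D = A[:, sl] - Abar[:, None]
        sigma += (D * (psi**2 / kap)) @ D.T
        cl0 += ni
    sigma *= scheme.g_n
    sigma = 0.5 * (sigma + sigma.T)
    return CovarianceFit(
        sigma_hat=sigma,
        A_hats=A,
        kappa=kappa,
        group_of_cluster=flat.group_of_cl,
        psi_cl=flat.psi_cl,
        g_n=scheme.g_n,
    )


def estimate_sigma_H0F(design: ClusteredDesign, scheme: WeightScheme) -> np.ndarray:
    """Diagonal variances for tests of equal distribution functions (H0F).

    Uses own-group placements ``Ŷ_ij = sum_k omega_ijk Fhat_{i,psi}(X_ijk)``:
    ``sigma_i^2 = sum_j psi_ij^2 / kappa_ij (Ŷ_ij - Ȳ_i.)^2``.  Returns the
    length-d vector (variances of the unscaled group means; multiply by g_n
    for the standardized scale).
    """
    if np.any(design.n_i < 2):
        raise DesignError("variance requires >=2 clusters per group")
    flat = _Flat(design, scheme)
    Y = _cluster_Y(flat)
    kap_by_group = kappa_factors(scheme)
    out = np.empty(flat.d)
    cl0 = 0
    for i in range(flat.d):
        ni = design.n_i[i]
        sl = slice(cl0, cl0 + ni)
        psi = flat.psi_cl[sl]
        Yi = Y[i, sl]
        Ybar = float(psi @ Yi)
        out[i] = float(np.sum(psi**2 / np.asarray(kap_by_group[i]) * (Yi - Ybar) ** 2))
        cl0 += ni
    return out
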