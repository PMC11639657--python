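"""Relative-effect estimation via normalized empirical distribution functions.

The estimand is the generalized relative effect

    p_i = int F_theta dF_i = P(G < X_i) + 1/2 P(G = X_i),   G ~ F_theta,

where ``F_theta = sum_i theta_i F_i`` is a weighted mean distribution and each
``F_i`` is the *normalized* distribution function (average of left- and
right-continuous versions), so ties and ordinal data are handled exactly.
Estimation plugs in weighted empirical distribution functions; with the
weighted preset the placements are classical mid-ranks, with the unweighted
preset they are pseudo-ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ClusteredDesign, WeightScheme

__all__ = ["EffectFit", "edf_value", "estimate_effects", "effect_oracle", "ranks"]


# ---------------------------------------------------------------------------
# flattened internal representation (shared with the variance module)


class _Flat:
    """Arrays indexed by observation / cluster for vectorized computation."""

    def __init__(self, design: ClusteredDesign, scheme: WeightScheme):
        vals, g_obs, cl_obs, w_obs = [], [], [], []
        psi_cl, g_cl = [], []
        cl = 0
        for i, grp in enumerate(design.clusters):
            for j, vec in enumerate(grp):
                vals.append(np.asarray(vec, float))
                g_obs.append(np.full(len(vec), i, dtype=np.intp))
                cl_obs.append(np.full(len(vec), cl, dtype=np.intp))
                w_obs.append(np.asarray(scheme.omega[i][j], float))
                psi_cl.append(scheme.psi[i][j])
                g_cl.append(i)
                cl += 1
        self.values = np.concatenate(vals)
        self.group_of_obs = np.concatenate(g_obs)
        self.cluster_of_obs = np.concatenate(cl_obs)
        self.omega_obs = np.concatenate(w_obs)
        self.psi_cl = np.asarray(psi_cl, float)
        self.group_of_cl = np.asarray(g_cl, np.intp)
        self.theta = np.asarray(scheme.theta, float)
        self.d = design.d
        self.n_cl = cl
        self.M = len(self.values)

    def group_edf_at(self, values: np.ndarray) -> np.ndarray:
        """Matrix ``F[c, t] = Fhat_{c,psi}(values[t])`` for all groups c."""
        out = np.empty((self.d, len(values)))
        for c in range(self.d):
            sel = self.group_of_obs == c
            pts = self.values[sel]
            mass = self.omega_obs[sel] * self.psi_cl[self.cluster_of_obs[sel]]
            out[c] = edf_value(pts, mass, values)
        return out


def edf_value(points, masses, x):
    """Normalized weighted EDF of a point-mass set, evaluated at ``x``.

    Returns ``sum_t masses[t] * (1{points[t] < x} + 1/2 * 1{points[t] = x})``
    (vectorized over ``x``).  Masses must sum to 1 for a proper EDF but this
    is not enforced here; ties are resolved by exact float equality.
    """
    points = np.asarray(points, float)
    masses = np.asarray(masses, float)
    order = np.argsort(points, kind="mergesort")
    pts = points[order]
    cum = np.concatenate(([0.0], np.cumsum(masses[order])))
    x = np.asarray(x, float)
    lo = np.searchsorted(pts, x, side="left")
    hi = np.searchsorted(pts, x, side="right")
    return cum[lo] + 0.5 * (cum[hi] - cum[lo])


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectFit:
    """Estimated relative effects and the placements behind them.

    ``placements`` holds ``Fhat_theta(X_ijk)`` per observation in flat order,
    ``group_edfs[c, t]`` holds ``Fhat_{c,psi}`` evaluated at observation ``t``.
    """

    p_hat: np.ndarray
    scheme: WeightScheme
    placements: np.ndarray
    group_edfs: np.ndarray

    @property
    def d(self) -> int:
        return len(self.p_hat)


def estimate_effects(design: ClusteredDesign, scheme: WeightScheme) -> EffectFit:
    """Plug-in estimator ``p̂_i = sum_j psi_ij sum_k omega_ijk Fhat_theta(X_ijk)``.

    Computed through placements (one EDF evaluation per observation); the
    weighted identity ``sum_i theta_i p̂_i = 1/2`` holds by construction.
    """
    flat = _Flat(design, scheme)
    G = flat.group_edf_at(flat.values)  # d x M
    placements = flat.theta @ G
    w = flat.omega_obs * flat.psi_cl[flat.cluster_of_obs]
    p_hat = np.zeros(flat.d)
    np.add.at(p_hat, flat.group_of_obs, w * placements)
    return EffectFit(p_hat=p_hat, scheme=scheme, placements=placements, group_edfs=G)


def effect_oracle(design: ClusteredDesign, scheme: WeightScheme) -> np.ndarray:
    """Brute-force double sum over all weighted observation pairs.

    Evaluates ``p̂_i = sum_s theta_s sum_{jk} psi_ij omega_ijk sum_{j'k'}
    psi_sj' omega_sj'k' [1(X_s < X_i) + 1/2 1(=)]`` literally in O(M^2);
    intended as an independent check of :func:`estimate_effects` on small
    designs.
    """
    flat = _Flat(design, scheme)
    w = flat.omega_obs * flat.psi_cl[flat.cluster_of_obs]  # within-group mass
    x = flat.values
    d = flat.d
    p = np.zeros(d)
    for i in range(d):
        sel_i = flat.group_of_obs == i
        total = 0.0
        for t in np.nonzero(sel_i)[0]:
            acc = 0.0
            for s in range(d):
                sel_s = flat.group_of_obs == s
                less = (x[sel_s] < x[t]).astype(float)
                eq = (x[sel_s] == x[t]).astype(float)
                acc += flat.theta[s] * np.sum(w[sel_s] * (less + 0.5 * eq))
            total += w[t] * acc
        p[i] = total
    return p


def ranks(design: ClusteredDesign, scheme: WeightScheme):
    """Global and group-internal (pseudo-)ranks per observation.

    Returns ``(R, R_int)`` in flat observation order with
    ``R_ijk = M * Fhat_theta(X_ijk) + 1/2`` and
    ``R^(i)_ijk = M_i * Fhat_{i,psi}(X_ijk) + 1/2``.  Under the weighted
    preset these are the classical mid-ranks over all M (resp. M_i)
    observations; under the unweighted preset they are pseudo-ranks.
    """
    flat = _Flat(design, scheme)
    G = flat.group_edf_at(flat.values)
    M_i = design.M_i
    R = design.M * (flat.theta @ G) + 0.5
    R_int = M_i[flat.group_of_obs] * G[flat.group_of_obs, np.arange(flat.M)] + 0.5
    return R, R_int
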