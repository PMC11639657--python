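"""Simulation designs for type-I error and power studies of the clustered
rank procedures.

Clusters are drawn as Gaussian copulas: a latent multivariate normal vector
with a specified within-cluster correlation matrix is mapped through the
standard normal CDF and then through the marginal quantile function
(normal marginals are generated directly).  Correlation structures are
"none", "homogeneous" (equicorrelation rho_max) or "heterogeneous" (outer
product of U(rho_min, rho_max) loadings with unit diagonal).  Imbalance rules
perturb cluster sizes and group sizes mildly (uniform draws in a +/-3 window,
floored at 2) or severely (one cluster of size 2 and one of 15 per group; one
group of 8 and one of 25 clusters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import ClusteredDesign, make_scheme, contrast
from .effects import estimate_effects
from .variance import estimate_sigma
from .global_tests import wald_test, anova_test, DegenerateCovarianceError
from .mctp import mctp

__all__ = [
    "SimModel",
    "StudyResult",
    "TYPE1_MODELS",
    "POWER_MODELS",
    "get_model",
    "gen_correlation",
    "gen_cluster_sizes",
    "gen_group_sizes",
    "gen_sample",
    "run_study",
]


@dataclass(frozen=True)
class SimModel:
    """A named simulation condition (marginal, dependence, imbalance, scheme)."""

    name: str
    marginal: str  # normal | beta | poisson | binomial
    correlation: str = "none"  # none | homogeneous | heterogeneous
    rho_min: float = 0.0
    rho_max: float = 0.0
    cluster_imbalance: str = "none"  # none | mild | severe
    group_imbalance: str = "none"
    scheme: str = "unweighted"  # pseudo-rank (unweighted) or rank (weighted)
    variance_rule: str = "identical"  # identical | bf (sd_i = 0.1 i^2)
    alternative: bool = False  # use the shift-alternative parametrization

    def __post_init__(self):
        if not (0.0 <= self.rho_min <= self.rho_max < 1.0):
            raise ValueError("need 0 <= rho_min <= rho_max < 1")

    def marginal_params(self, i: int, r: float = 0.0) -> tuple:
        """Marginal parameters of group ``i`` (1-based) at shift ``r``.

        Null models use identical marginals; alternatives shift them with r:
        normal mu_i = r*i, sd_i = 0.7 + 0.1*i; beta (2 + r(i-1), 4 - r(i-1));
        Poisson lambda_i = 5 + r*i.
        """
        if self.marginal == "normal":
            if self.alternative:
                return (r * i, 0.7 + 0.1 * i)
            if self.variance_rule == "bf":
                return (0.0, 0.1 * i**2)
            return (0.0, 1.0)
        if self.marginal == "beta":
            if self.alternative:
                return (2.0 + r * (i - 1), 4.0 - r * (i - 1))
            return (2.0, 5.0)
        if self.marginal == "poisson":
            return (5.0 + r * i,) if self.alternative else (5.0,)
        if self.marginal == "binomial":
            return (5, 0.6)
        raise ValueError(f"unknown marginal {self.marginal!r}")


def _t1(name, marginal, corr, lo, hi, imb="none", scheme="unweighted", var="identical"):
    return SimModel(
        name=name, marginal=marginal, correlation=corr, rho_min=lo, rho_max=hi,
        cluster_imbalance=imb, group_imbalance=imb, scheme=scheme, variance_rule=var,
    )


TYPE1_MODELS = {
    m.name: m
    for m in [
        _t1("1.1", "normal", "none", 0, 0),
        _t1("1.2", "normal", "homogeneous", 0, 0.85),
        _t1("1.3", "normal", "heterogeneous", 0.05, 0.35),
        _t1("2", "beta", "homogeneous", 0, 0.35),
        _t1("3", "poisson", "heterogeneous", 0.6, 0.85),
        _t1("4.1", "normal", "heterogeneous", 0.05, 0.35, imb="mild"),
        _t1("4.2", "normal", "heterogeneous", 0.05, 0.35, imb="mild", scheme="weighted"),
        _t1("5", "binomial", "homogeneous", 0, 0.85, imb="mild"),
        _t1("6.1", "normal", "heterogeneous", 0.6, 0.85, imb="severe"),
        _t1("6.2", "normal", "heterogeneous", 0.6, 0.85, imb="severe", scheme="weighted"),
        _t1("7", "poisson", "heterogeneous", 0.05, 0.35, imb="severe"),
        _t1("8.1", "normal", "heterogeneous", 0.6, 0.85, var="bf"),
        _t1("8.2.1", "normal", "heterogeneous", 0.6, 0.85, imb="mild", var="bf"),
        _t1("8.2.2", "normal", "heterogeneous", 0.6, 0.85, imb="mild", scheme="weighted", var="bf"),
        _t1("8.3.1", "normal", "heterogeneous", 0.6, 0.85, imb="severe", var="bf"),
        _t1("8.3.2", "normal", "heterogeneous", 0.6, 0.85, imb="severe", scheme="weighted", var="bf"),
    ]
}


def _pw(name, marginal, corr, lo, hi):
    return SimModel(
        name=name, marginal=marginal, correlation=corr, rho_min=lo, rho_max=hi,
        cluster_imbalance="mild", group_imbalance="mild", alternative=True,
    )


POWER_MODELS = {
    m.name: m
    for m in [
        _pw("power-1.1", "normal", "none", 0, 0),
        _pw("power-1.2", "normal", "homogeneous", 0, 0.85),
        _pw("power-1.3", "normal", "heterogeneous", 0.05, 0.35),
        _pw("power-2.1", "beta", "none", 0, 0),
        _pw("power-2.2", "beta", "homogeneous", 0, 0.85),
        _pw("power-2.3", "beta", "heterogeneous", 0.05, 0.35),
        _pw("power-3.1", "poisson", "none", 0, 0),
        _pw("power-3.2", "poisson", "homogeneous", 0, 0.85),
        _pw("power-3.3", "poisson", "heterogeneous", 0.05, 0.35),
    ]
}


def get_model(name: str) -> SimModel:
    if name in TYPE1_MODELS:
        return TYPE1_MODELS[name]
    if name in POWER_MODELS:
        return POWER_MODELS[name]
    raise KeyError(f"unknown simulation model {name!r}")


# ---------------------------------------------------------------------------
# building blocks


def gen_correlation(structure: str, rho_min: float, rho_max: float, m: int, rng) -> np.ndarray:
    """Within-cluster latent correlation matrix of size m."""
    if rho_max >= 1.0:
        raise ValueError("rho_max must be < 1")
    if m < 1:
        raise ValueError("m must be >= 1")
    if structure == "none" or m == 1:
        return np.eye(m)
    if structure == "homogeneous":
        R = np.full((m, m), rho_max)
    elif structure == "heterogeneous":
        load = rng.uniform(rho_min, rho_max, size=m)
        R = np.outer(load, load)
    else:
        raise ValueError(f"unknown correlation structure {structure!r}")
    np.fill_diagonal(R, 1.0)
    return R


def gen_cluster_sizes(imbalance: str, base_m: int, n_i: int, rng) -> np.ndarray:
    """Cluster sizes of one group under the imbalance rule (sizes >= 2 when varied)."""
    if imbalance == "none":
        return np.full(n_i, base_m, dtype=int)
    if imbalance == "mild":
        lo = max(base_m - 3, 2)
        return rng.integers(lo, base_m + 3 + 1, size=n_i)
    if imbalance == "severe":
        if n_i < 2:
            raise ValueError("severe imbalance needs n_i >= 2")
        sizes = np.full(n_i, base_m, dtype=int)
        sizes[0], sizes[1] = 2, 15
        return rng.permutation(sizes)
    raise ValueError(f"unknown imbalance {imbalance!r}")


def gen_group_sizes(imbalance: str, base_n: int, d: int, rng) -> np.ndarray:
    """Group-wise numbers of clusters under the imbalance rule."""
    if imbalance == "none":
        return np.full(d, base_n, dtype=int)
    if imbalance == "mild":
        return rng.integers(max(base_n - 3, 2), base_n + 3 + 1, size=d)
    if imbalance == "severe":
        if d < 2:
            raise ValueError("severe imbalance needs d >= 2")
        ns = np.full(d, base_n, dtype=int)
        ns[0], ns[1] = 8, 25
        return rng.permutation(ns)
    raise ValueError(f"unknown imbalance {imbalance!r}")


def _marginal_ppf(family: str, params: tuple):
    if family == "beta":
        return lambda u: stats.beta.ppf(u, *params)
    if family == "poisson":
        return lambda u: stats.poisson.ppf(u, params[0])
    if family == "binomial":
        return lambda u: stats.binom.ppf(u, *params)
    raise ValueError(family)


def gen_sample(
    model: SimModel,
    d: int,
    n_vec: np.ndarray,
    sizes,
    rng,
    r: float = 0.0,
) -> ClusteredDesign:
    """Draw one clustered design: ``sizes[i]`` are the cluster sizes of group i."""
    groups = tuple(range(1, d + 1))
    clusters = []
    ids = []
    chol_cache: dict = {}  # size -> factor; valid for none/homogeneous structures
    cacheable = model.correlation in ("none", "homogeneous")
    for gi, i in enumerate(groups):
        params = model.marginal_params(i, r)
        ppf = None if model.marginal == "normal" else _marginal_ppf(model.marginal, params)
        gcl = []
        for j in range(int(n_vec[gi])):
            m = int(sizes[gi][j])
            if cacheable and m in chol_cache:
                L = chol_cache[m]
            else:
                R = gen_correlation(model.correlation, model.rho_min, model.rho_max, m, rng)
                L = np.linalg.cholesky(R + 1e-12 * np.eye(m))
                if cacheable:
                    chol_cache[m] = L
            z = L @ rng.standard_normal(m)
            if model.marginal == "normal":
                mu, sd = params
                x = mu + sd * z
            else:
                u = np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12)
                x = np.asarray(ppf(u), float)
            gcl.append(x)
        clusters.append(tuple(gcl))
        ids.append(tuple(range(1, int(n_vec[gi]) + 1)))
    return ClusteredDesign(groups, tuple(clusters), tuple(ids))


# ---------------------------------------------------------------------------
# rejection-rate studies


@dataclass(frozen=True)
class StudyResult:
    """Empirical rejection rates of the three tests under one condition."""

    rates: dict  # test name -> rejection proportion
    mc_se: dict  # test name -> sqrt(p(1-p)/reps)
    reps: int
    alpha: float
    seed: int
    config: dict
    failures: int = 0  # replicates where a test raised a degeneracy error

    def as_rows(self):
        for test, rate in self.rates.items():
            row = {"test": test, "rejection_rate": rate, "mc_se": self.mc_se[test],
                   "reps": self.reps, "alpha": self.alpha, "seed": self.seed}
            row.update(self.config)
            yield row


def run_study(
    model: SimModel,
    d: int,
    n_base: int,
    base_m: int,
    reps: int,
    alpha: float = 0.05,
    seed: int = 0,
    r: float = 0.0,
    contrast_kind: str = "centering",
    mctp_tol: float = 2e-3,
) -> StudyResult:
    """Monte-Carlo rejection rates of Wald, ANOVA-F and MCTP (t, Fisher).

    Each replicate draws a design from ``model``, fits both the effects and
    the covariance under the model's weighting preset and records whether
    each test rejects at level ``alpha`` with the given contrast family.
    Fully reproducible from ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(reps)
    C = contrast(contrast_kind, d)
    hits = {"wald": 0, "anova_f": 0, "mctp": 0}
    failures = 0
    for child in children:
        rng = np.random.default_rng(child)
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        n_vec = gen_group_sizes(model.group_imbalance, n_base, d, rng)
        sizes = [
            gen_cluster_sizes(model.cluster_imbalance, base_m, int(ni), rng)
            for ni in n_vec
        ]
        design = gen_sample(model, d, n_vec, sizes, rng, r=r)
        scheme = make_scheme(design, model.scheme)
        try:
            fit = estimate_effects(design, scheme)
            cov = estimate_sigma(design, scheme, fit)
            if wald_test(fit, cov, C).p_value <= alpha:
                hits["wald"] += 1
            if anova_test(design, scheme, fit, cov, C, approx="F").p_value <= alpha:
                hits["anova_f"] += 1
            res = mctp(
                design, scheme, C, alpha=alpha, approx="t", transform="fisher",
                tol=mctp_tol, seed=sub_seed, fit=fit, cov=cov, detail="global",
            )
            if res.p_global <= alpha:
                hits["mctp"] += 1
        except DegenerateCovarianceError:
            failures += 1
    rates = {k: v / reps for k, v in hits.items()}
    mc_se = {k: float(np.sqrt(p * (1 - p) / reps)) for k, p in rates.items()}
    config = {
        "model": model.name, "d": d, "n": n_base, "m": base_m, "r": r,
        "contrast": contrast_kind, "scheme": model.scheme,
    }
    return StudyResult(rates=rates, mc_se=mc_se, reps=reps, alpha=alpha,
                       seed=seed, config=config, failures=failures)
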