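"""End-to-end analysis of a clustered dataset: effect table, contrast table
and global tests, mirroring the reporting style of nonparametric factorial
analyses (per-group relative effects with simultaneous confidence intervals,
per-contrast estimates with adjusted p-values, and the global test summary).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ClusteredDesign, ContrastMatrix, make_scheme
from .effects import estimate_effects
from .variance import estimate_sigma
from .global_tests import wald_test, anova_test, global_test_H0F
from .mctp import mctp, satterthwaite_df, fisher_sci
from .mvquant import equicoordinate_quantile, DEFAULT_SEED

__all__ = ["AnalysisReport", "analyze", "group_sci"]


@dataclass(frozen=True)
class AnalysisReport:
    """Tabular results of one analysis run.

    ``group_table``: per-group effect estimate, standard deviation
    (sqrt of the diagonal of the covariance of sqrt(g_n)(p̂-p)) and
    simultaneous CI for p_i.  ``contrast_table``: per-contrast estimate, SD,
    simultaneous CI and adjusted p-value.  ``global_table``: one row per
    global test.  ``info``: scheme, df, critical value and R_hat.
    """

    group_table: pd.DataFrame
    contrast_table: pd.DataFrame
    global_table: pd.DataFrame
    info: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.group_table.to_csv(out / "groups.csv", index=False)
        self.contrast_table.to_csv(out / "contrasts.csv", index=False)
        self.global_table.to_csv(out / "global_tests.csv", index=False)
        (out / "report.txt").write_text(self.render())

    def render(self) -> str:
        info = self.info
        lines = [
            "Nonparametric relative-effect analysis (clustered data)",
            f"scheme: {info['scheme']}  g_n: {info['g_n']:g}  "
            f"alpha: {info['alpha']:g}  approx: {info['approx']}  "
            f"transform: {info['transform']}",
            f"df (nu_hat): {info['nu_hat']:.3f}  critical value: {info['crit']:.4f}",
            "",
            "Relative effects (simultaneous CIs):",
            self.group_table.round(2).to_string(index=False),
            "",
            "Contrasts:",
            self.contrast_table.round(2).to_string(index=False),
            "",
            "Global tests:",
            self.global_table.round(4).to_string(index=False),
            "",
        ]
        return "\n".join(lines)


def group_sci(design, scheme, alpha=0.05, approx="t", transform="fisher",
              seed=DEFAULT_SEED, fit=None, cov=None):
    """Simultaneous confidence intervals for the effects p_1..p_d themselves.

    Treats the centered effects delta_i = p_i - 1/2 with the identity
    coefficient matrix through the same multivariate machinery (joint
    normal/t of all d standardized effect estimates), then shifts the
    Fisher-scale intervals back by 1/2.
    """
    if fit is None:
        fit = estimate_effects(design, scheme)
    if cov is None:
        cov = estimate_sigma(design, scheme, fit)
    d = design.d
    I = np.eye(d)
    sigma = cov.sigma_hat
    sd = np.sqrt(np.diag(sigma))
    if np.any(sd <= 0):
        # no information for some group; report NaN intervals there
        sd = np.where(sd > 0, sd, np.nan)
    R_hat = sigma / np.outer(sd, sd)
    np.fill_diagonal(R_hat, 1.0)
    R_hat = np.nan_to_num(R_hat, nan=0.0)
    if approx == "t":
        nu_hat, _ = satterthwaite_df(design, scheme, cov.A_hats, _Identity(I))
    else:
        nu_hat = np.inf
    crit = equicoordinate_quantile(R_hat, nu_hat, alpha, seed=seed)
    delta = fit.p_hat - 0.5
    if transform == "fisher":
        lo, hi, _ = fisher_sci(delta, sigma, scheme.g_n, crit)
    else:
        half = crit * sd / np.sqrt(scheme.g_n)
        lo, hi = delta - half, delta + half
    return lo + 0.5, hi + 0.5, sd, crit, nu_hat


class _Identity:
    """Coefficient-matrix shim (identity rows are not zero-sum contrasts)."""

    def __init__(self, entries):
        self.entries = entries


def analyze(
    design: ClusteredDesign,
    scheme: str = "unweighted",
    C: ContrastMatrix | None = None,
    alpha: float = 0.05,
    approx: str = "t",
    transform: str = "fisher",
    tests: str = "all",
    h0f: bool = False,
    seed: int = DEFAULT_SEED,
) -> AnalysisReport:
    """Run the full inference pipeline on a clustered design."""
    from .design import contrast as make_contrast

    sch = make_scheme(design, scheme)
    if C is None:
        C = make_contrast("tukey", design.d)
    fit = estimate_effects(design, sch)
    cov = estimate_sigma(design, sch, fit)

    res = mctp(design, sch, C, alpha=alpha, approx=approx, transform=transform,
               seed=seed, fit=fit, cov=cov)
    glo, ghi, gsd, gcrit, gnu = group_sci(
        design, sch, alpha=alpha, approx=approx, transform=transform,
        seed=seed, fit=fit, cov=cov,
    )
    group_table = pd.DataFrame({
        "group": list(design.groups),
        "estimator": fit.p_hat,
        "std_dev": gsd,
        "lower": glo,
        "upper": ghi,
    })
    contrast_table = pd.DataFrame({
        "contrast": list(res.labels),
        "estimator": res.delta_hat,
        "std_dev": res.se * np.sqrt(sch.g_n),
        "lower": res.sci_lower,
        "upper": res.sci_upper,
        "p_value": res.p_adjusted,
    })
    rows = []
    want = lambda name: tests in ("all", name)
    if want("wald"):
        w = wald_test(fit, cov, C)
        rows.append(("wald", w.statistic, w.df[0], np.inf, w.p_value))
    if want("anova"):
        a = anova_test(design, sch, fit, cov, C, approx="F")
        rows.append(("anova_f", a.statistic, a.df[0], a.df[1], a.p_value))
    if want("mctp"):
        rows.append(("mctp_max", res.global_statistic, res.nu_hat, np.nan, res.p_global))
    if h0f:
        for kind in ("wald", "anova"):
            hres = global_test_H0F(design, sch, C, kind=kind)
            rows.append((hres.method, hres.statistic, hres.df[0], hres.df[1], hres.p_value))
    global_table = pd.DataFrame(rows, columns=["method", "statistic", "df1", "df2", "p_value"])
    info = {
        "scheme": scheme, "g_n": sch.g_n, "alpha": alpha, "approx": approx,
        "transform": transform, "nu_hat": res.nu_hat,
        "crit": res.crit, "R_hat": res.R_hat, "group_crit": gcrit, "group_nu": gnu,
    }
    return AnalysisReport(group_table, contrast_table, global_table, info)
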