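"""Global tests of equal relative effects (and equal distributions) across
groups of clustered observations.

Uses a synthetic bilateral ordinal dataset with four groups.  The Wald-type
test is asymptotically exact but liberal in small samples; the ANOVA-type
test with F(f1, f2) approximation is the recommended global test.
"""

from clustrank import (
    contrast,
    design_from_frame,
    estimate_effects,
    estimate_sigma,
    global_test_H0F,
    make_scheme,
    anova_test,
    wald_test,
)
from clustrank.datasets import moyamoya_like

des = design_from_frame(moyamoya_like(seed=1))
sch = make_scheme(des, "unweighted")
fit = estimate_effects(des, sch)
cov = estimate_sigma(des, sch, fit)
C = contrast("centering", des.d)  # H0: p_1 = ... = p_4

w = wald_test(fit, cov, C)
a = anova_test(des, sch, fit, cov, C, approx="F")
print(f"Wald-type:  Q = {w.statistic:.3f}, chi2 df = {w.df[0]:.0f}, p = {w.p_value:.3f}")
print(f"ANOVA-type: Q = {a.statistic:.3f}, F({a.df[0]:.2f}, {a.df[1]:.2f}), p = {a.p_value:.3f}")

# The stricter hypothesis of equal distribution functions (H0F) uses a
# diagonal covariance of the groupwise mean placements:
h = global_test_H0F(des, sch, C, kind="anova")
print(f"H0F ANOVA:  Q = {h.statistic:.3f}, p = {h.p_value:.3f}")
# Large p-values: the synthetic grades do not differ detectably across groups.
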