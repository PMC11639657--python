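# Methods

## Model and estimands

The data are a one-way layout of `d >= 2` independent samples (groups).
Sample `i` consists of `n_i` independent clusters; cluster `j` holds
`m_ij >= 1` replicate observations `X_ijk` that share the marginal
distribution `F_i` but may be arbitrarily dependent within the cluster
(two hemispheres of a patient, teeth of a subject, animals in a cage).  No
dependency structure is modelled or assumed; clusters are the independent
units.  All distribution functions are used in their *normalized* form
`F = (F^- + F^+)/2`, which makes every quantity below well defined for
metric, ordinal and dichotomous data and handles ties exactly.

The estimand for group `i` is the generalized relative (Wilcoxon–Mann–
Whitney) effect

    p_i = ∫ F_θ dF_i = P(G < X_ijk) + 1/2 P(G = X_ijk),   G ~ F_θ,

where `F_θ = Σ_i θ_i F_i` is a weighted mean reference distribution.
`p_i < 1/2` means observations from group `i` tend to be smaller than a draw
from the reference.  Hypotheses are linear: `H0: Cp = 0` for a matrix whose
rows sum to zero (all-pairwise, many-to-one, or the centering matrix
`I_d - 11'/d` for the global hypothesis `p_1 = ... = p_d`).  Pairwise-defined
effects `P(X_i < X_j)` are deliberately not used; they are non-transitive
(Efron dice) and a common reference distribution avoids that.

## Weights

Three weight layers define both the estimand and the estimator:

| symbol | domain | role | presets |
|---|---|---|---|
| `ω_ijk` | within cluster | weight of a replicate, `Σ_k ω_ijk = 1` | `1/m_ij` |
| `ψ_ij` | within group | weight of a cluster, `Σ_j ψ_ij = 1` | `1/n_i` (unweighted), `m_ij/M_i` (weighted) |
| `θ_i` | across groups | reference mixture, `Σ_i θ_i = 1` | `1/d` (unweighted), `M_i/M` (weighted) |

The *unweighted* preset (pseudo-rank scheme, normalization `g(n) = n`, the
total cluster count) defines effects free of sample-size allocation and is
the default and the recommended choice.  The *weighted* preset (classical
mid-ranks, `g(n) = M`, the total observation count) reproduces the
rank-procedure tradition but makes the estimand depend on group sizes.
Custom weights (e.g. inverse-size or reliability weightings) are accepted
as long as they are non-negative and normalized; variance-based `θ` is left
to the user because no canonical plug-in exists for ordinal data.

## Estimation

Plugging weighted empirical distribution functions
`F̂_iψ = Σ_j ψ_ij Σ_k ω_ijk F̂_ijk` into the integral gives

    p̂_i = Σ_j ψ_ij Σ_k ω_ijk F̂_θ(X_ijk),

a weighted sum of placements.  The implementation evaluates each group EDF
at all M observations via sorted arrays (O(M log M)); a literal O(M²)
double-sum oracle is kept in the API and the identity between the two is a
standing test.  By construction `Σ_i θ_i p̂_i = 1/2` exactly and
`θ_i/2 <= p̂_i <= 1 - θ_i/2`.  Ties are resolved by exact float equality of
the stored values (the half-weight terms must be exact, not tolerance
based); any order-preserving numeric coding of ordinal data gives identical
results, and all statistics are invariant under strictly increasing
transformations of the data.

## Covariance estimation

`√g(n) (p̂ - p)` is asymptotically normal with a covariance `Σ` estimated
through per-cluster summaries: with `Ŷ_ij^(c) = Σ_k ω_ijk F̂_cψ(X_ijk)`,
the cluster vector `Â_ij` has component `Σ_{s≠i} θ_s Ŷ_ij^(s)` in its own
group's position and `-θ_i Ŷ_ij^(h)` elsewhere (only cross-group placements
carry information).  The estimator

    Σ̂ = g(n) Σ_i Σ_j ψ_ij² κ_ij⁻¹ (Â_ij - Ā_i·)(Â_ij - Ā_i·)',
    κ_ij = 1 - 2ψ_ij + Σ_j' ψ_ij'²,

uses the per-cluster correction `κ_ij ∈ (0, 1]` that removes the bias of the
weighted centering; it requires `n_i >= 2` everywhere (with a single cluster
`κ = 0`).  A Monte-Carlo test verifies unbiasedness of the true-`F` analogue
against the empirical variance of `√g(n) p̂`.  Under the stricter hypothesis
of equal distribution functions (H0F) the covariance is diagonal and is
estimated from own-group placements only.

## Tests

*Wald-type*: `Q_w = g(n) p̂'C'(CΣ̂C')⁺Cp̂` against chi-square with
`rank(CΣ̂C')` degrees of freedom.  Pseudo-inverse and rank use a relative
singular-value cutoff of 1e-8.  Liberal in small samples; included for
completeness and as the power envelope.

*ANOVA-type*: `Q_a = g(n) p̂'Mp̂ / tr(MΣ̂)` with the row-space projection
`M = C'(CC')⁻C` (depends on the row space of `C` only).  The reference is
`F(f̂1, f̂2)` with the Box-type `f̂1 = tr(MΣ̂)²/tr(MΣ̂MΣ̂)` and a rank-based
`f̂2` built from groupwise dispersions of global-minus-internal ranks; a
chi-square variant (`χ²_{f̂1}/f̂1`, no `f̂2`) is retained because it is the
historically used, more liberal approximation.  Global ranks are computed
as `R_ijk = M·F̂_θ(X_ijk) + 1/2` and internal ranks as
`R^(i)_ijk = M_i·F̂_iψ(X_ijk) + 1/2`; the factor `M` (total observations) is
the choice under which the weighted preset reproduces textbook mid-ranks,
and with one observation per cluster the cluster count and `M` coincide.
In that reduction with `d = 2` and the weighted preset, the ANOVA-type test
is algebraically the Brunner–Munzel test (statistic and df agree to
floating-point accuracy; this is a standing test against an independent
direct implementation).

*MCTP*: per contrast `T_l = √(g(n)/Υ̂_ll) c_l'p̂` with `Υ̂ = CΣ̂C'`, jointly
referred to a multivariate normal (large samples) or central multivariate t
(default) with correlation `R̂ = diag(Υ̂)^{-1/2} Υ̂ diag(Υ̂)^{-1/2}` and one
family-wide Satterthwaite–Welch df

    ν̂ = max{1, min_l ν̂_l},
    ν̂_l = (Σ_i v̂_li²)² / Σ_i v̂_li⁴/(n_i-1),
    v̂_li² = Σ_j ψ_ij² κ_ij⁻¹ (c_l'Â_ij - mean)².

The `ψ²κ⁻¹` weighting is the one consistent with the covariance estimator
(it makes `Σ_i v̂_li² = Υ̂_ll/g(n)` an identity) and the one under which the
two-sample reduction reproduces the Brunner–Munzel df exactly.  Rejection
uses the two-sided equicoordinate quantile; adjusted p-values are
`1 - P(all |T| <= |t_l,obs|)` under the fitted joint distribution (standard
single-step convention), so the global max-test p-value equals the smallest
adjusted p-value (consonance holds by construction).

*Scaling convention.* Throughout, the standardized vector is `√g(n)(p̂-p)`,
`Σ̂` estimates its covariance, and interval half-widths are
`crit·√(Υ̂_ll/g(n))`.  This is the only internally consistent reading of the
estimator/statistic/interval triple and is what the type-I error studies
validate.

## Fisher-scale simultaneous intervals

Contrast effects live in (-1, 1), and raw Wald intervals can escape that
range.  For normed contrasts (`max_i |c_li| <= 1`) the delta method on
`ζ(x) = artanh(x)` gives `Γ̂ = η̂Υ̂η̂'`, `η̂ = diag(1/(1-δ̂_l²))`; intervals
`tanh(ζ(δ̂_l) ∓ crit·√(Γ̂_ll/g(n)))` are range-preserving and the
transformation leaves the correlation matrix `R̂` unchanged.  The default
reporting combination is multivariate t plus Fisher transform — the
combination with the best small-sample level in the validation studies.
Estimates on the boundary `|δ̂| = 1` are clipped to `1 - 1e-12` with a
warning; at that extreme the back-transformed bound can round to exactly
±1.0 in double precision.

Per-group simultaneous intervals for `p_i` itself (the descriptive table)
apply the identical machinery to the centered effects `δ_i = p_i - 1/2`
with the identity coefficient matrix and shift back; the reported per-group
"standard deviation" is `√Σ̂_ii` on the `√g(n)` scale.  This construction is
a package choice: descriptive intervals for the effects are not otherwise
pinned down by the testing framework.

## Equicoordinate probabilities

`P(|T_1| <= c, ..., |T_q| <= c)` is computed by Genz's sequential
conditioning transform on a scrambled Sobol sequence with 8 independent
random shifts (1024 points each, quadrupled until the shift-based standard
error is below `tol`, default 5e-4).  The multivariate t case adds one
chi-square scale dimension.  All randomness comes from one seed (default
20241111, overridable), so critical values are bit-for-bit reproducible;
quantiles are found by bracketing plus bisection on the *same* point set,
which makes the evaluated function exactly monotone in `c`.  Indefinite
`R̂` from floating point is repaired by eigenvalue clipping and diagonal
renormalization.  scipy's `multivariate_normal`/`multivariate_t` CDFs serve
as an independent cross-check in the tests, not as the implementation.

## Simulation harness

The generator reproduces the validation conditions: marginals are standard
normal, `beta(2,5)`, `Poisson(5)`, `binomial(5, 0.6)`, or heteroscedastic
normals (`sd_i = 0.1 i²`); shift alternatives use `μ_i = r·i`,
`sd_i = 0.7 + 0.1 i` (normal), `(2 + r(i-1), 4 - r(i-1))` (beta),
`λ_i = 5 + r·i` (Poisson).  Within-cluster dependence is a Gaussian copula:
a latent normal vector with equicorrelation `ρ_max` (homogeneous) or the
unit-diagonal outer product of `U(ρ_min, ρ_max)` loadings (heterogeneous),
mapped through `Φ` and the marginal quantile function.  The copula
correlation is used as specified without Pearson-matching adjustment; the
joint law behind the published conditions is not fully pinned down by
marginals plus correlation, and the Gaussian copula is the simplest
construction consistent with them.  Mild imbalance draws cluster sizes from
`{max(m*-3, 2), ..., m*+3}` and group sizes from a ±3 window; severe
imbalance fixes one cluster at 2 and one at 15 per group, and one group at
8 and one at 25 clusters.

What the generator does *not* emulate: informative cluster sizes (size
correlated with outcome), missing replicates within clusters, covariates,
and non-Gaussian dependence (e.g. tail dependence).  Passing level/power
tests therefore demonstrate calibration under exchangeable-within-cluster
dependence with non-informative sizes, not robustness to those features.

Rejection-rate studies derive one child seed per replicate from a root
seed; the MCTP decision inside the loop needs only one rectangle
probability per replicate (no quantile search).  The packaged validation
studies use 2000 replicates for level (acceptance band ±0.015 = 3 MC
standard errors around 0.05) and 1000 for power curves; these sizes give
MC noise well below the effects being checked while keeping the default
test run quick.

## Degenerate inputs and numerical edge cases

- Constant data (or any `CΣ̂C'` of rank 0) raise a dedicated degeneracy
  error rather than returning a p-value; the CLI maps this to exit code 3.
- A group with a single cluster cannot contribute a variance (`κ = 0`);
  covariance estimation refuses with a clear message.
- `ν̂` has a floor of 1; if every contrast variance component vanishes the
  df is flagged infinite and the t reference degrades to the normal.
- Contrast matrices must have zero row sums and no zero rows; row rank may
  be deficient (centering, all-pairwise), which the quadratic forms handle
  by pseudo-inverse/row-space projection and the MCTP by construction.

## Known limitations

- No covariate adjustment; the framework is a one-way layout.
- No step-down or closed-testing refinement of the single-step MCTP.
- No model-based (structured) covariance estimation; the estimator is
  purely empirical, so very small cluster counts per group (`n_i < ~7`)
  rely on the conservative df floor rather than on accuracy of `Σ̂`.
- The weighted (classical-rank) preset is known to misbehave under severe
  imbalance; the pseudo-rank preset is the default for that reason.
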