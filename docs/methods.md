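# Methods

## Setting

A randomized controlled trial measures a continuous biomarker X, assigns
a treatment indicator T ∈ {0, 1} with probability ½ each, and observes a
continuous outcome Y. The treatment-effect function

    θ(x) = E(Y | X = x, T = 1) − E(Y | X = x, T = 0)

is the expected benefit of the new over the standard treatment at marker
value x; positive θ(x) favours the new treatment. A *treatment selection
rule* is a subset C of marker values: future patients with x ∈ C receive
the new treatment. `trtselect` implements four construction principles
that turn an estimate θ̂(·) and its sampling uncertainty into such a set
(threshold 0, closed "≥" convention):

| rule | definition |
|------|------------|
| EST  | C = {x : θ̂(x) ≥ 0} |
| POI  | C = {x : lower bound of the pointwise (1−γ) band ≥ 0} |
| SIM  | C = {x : lower bound of the simultaneous (1−γ) band ≥ 0} |
| CIR  | C = {x : θ̂(x) ≥ 0} \ ⋃ CI(x_r) over the roots x_r of θ̂ |

All four are gated by an interaction pretest: if the treatment–marker
interaction is not significant at the 5% level, every rule returns the
empty set.

## Estimation model

θ(x) is estimated by OLS on the interaction model with design columns
(1, x, t, t·x) (linear) or (1, x, x², t, t·x, t·x²) (quadratic). The
"treatment block" g — the coefficients of t and its interactions — gives
θ̂(x) = a(x)ᵀg with a(x) = (1, x[, x²]), pointwise standard error
se(x) = √(a(x)ᵀ Σ a(x)) from the block covariance Σ, and residual
degrees of freedom n − k. The pretest is the F-test of the interaction
coefficients (1 numerator df linear, 2 quadratic; for the linear model it
equals the squared t-statistic of the t·x coefficient), with strict
inequality p < level for significance. Plain homoscedastic OLS only: the
data model has normal errors with constant variance, so robust
covariances would add nothing here.

## Uncertainty objects

**Pointwise band.** θ̂(x) ± t_{df, 1−γ/2}·se(x); exact t coverage at each
x under the normal error model.

**Simultaneous band.** θ̂(x) ± c·se(x) with a single sup-t critical value
c: with Z ~ N(0, Σ), the band-deviation process a(x)ᵀZ/se(x) is simulated
from a large set of standard-normal draws mapped through the Cholesky
factor of Σ, its absolute supremum is taken over a 201-point grid of
[0, 1], and c is the (1−γ) quantile of the simulated suprema. The draws
come from a fixed sub-seed and are shared across calls, so critical
values are deterministic and differences across replicates reflect only
the fitted covariance. c is validated against the bracketing
t_{df, 1−γ/2} ≤ c ≤ √(d·F_{d, df, 1−γ}) (Scheffé) and by empirical
coverage. The sup-t calibration uses normal rather than t quantiles — at
n = 1500 the df correction is in the third decimal — and its contract is
the verified coverage, not a particular closed form. Default draw count:
100 000 for direct calls; the simulation engine uses 20 000 per
replicate, which perturbs c by well under 0.01 (quantile Monte Carlo
error ≈ √(γ(1−γ)/B)/φ(c)) while cutting the per-replicate cost an order
of magnitude below the rest of the pipeline; both are configurable.

**Root intervals.** θ̂ is a polynomial of degree ≤ 2, so its roots are
closed-form. Each root r in [0, 1] receives a first-order delta-method
interval r ± z_{1−γ/2}·SE with ∂r/∂g_k = −r^k/θ̂′(r) and
SE = √(∇ᵀΣ∇), clipped to [0, 1]. Normal quantiles are standard for
delta-method intervals. For the linear model the root is a ratio of
coefficients, for which the delta approximation is known to be crude;
this is deliberate — POI and CIR are kept as genuinely different
constructions, and their disagreement is part of what the simulation
measures. If θ̂′(r) = 0 at a root (double root, or θ̂ ≡ 0) the interval is
undefined; CIR then excises the whole domain (maximally conservative)
and the event is counted in the study diagnostics. A double root is
reported once.

**Horizontal reading.** A pointwise band can be read horizontally: the
set {x : lower(x) ≤ θ_t ≤ upper(x)} is a (1−γ) confidence set for
θ^{-1}(θ_t). Squaring the band condition turns membership into a
polynomial inequality of degree ≤ 4, so the set is computed exactly; it
satisfies the identity C_POI = C_EST \ {band covers 0}, which is tested,
along with its ≈95% empirical coverage of the true root.

## Set computations

Selection sets are unions of disjoint closed intervals with exact
algebra (union, intersection, closed complement, difference) and
probability mass computed from the marker CDF. Rule boundaries solve
(a(x)ᵀg)² = c²·a(x)ᵀΣa(x): real roots of the degree-≤4 polynomial come
from companion-matrix root finding, cells between roots are classified
by the sign of the actual lower-bound function at midpoints (this
discards the spurious roots introduced by squaring, i.e. zeros of the
upper bound), and crossings are sharpened by Brent's method to ~1e−12.
Isolated tangency points (measure zero) are ignored. In the set
difference used by CIR, width-zero leftovers are dropped: a rule that
retains a single marker value selects no patients, and the power metric
accordingly counts a set as non-empty only if it has positive measure.

## Quality measures

For a future patient with marker X* distributed like the trial marker:

    sensitivity  = P(X* ∈ C | θ(X*) ≥ 0)
    specificity  = P(X* ∉ C | θ(X*) < 0)
    overall gain = E[θ(X*)·1{X* ∈ C}]

computed by integration against the true scenario — CDF masses for the
probabilities, adaptive quadrature (absolute tolerance 1e−9, intervals
split at the triangular density's kink, verified against closed-form
polynomial integrals to 1e−8) for the gain — never by resampling future
patients, which removes one layer of Monte Carlo noise. The benchmark is
the maximal gain, the gain of the oracle set {θ ≥ 0}. Conventions: the
empty set has sensitivity 0, specificity 1, gain 0; at β = 0 no patient
has θ < 0 and specificity is defined as 1 (the aggregate summaries stay
defined; nothing in the standard study evaluates metrics at β = 0).

## Simulated worlds

The generator draws X by inverse-CDF transform (uniform on [0, 1], or
triangular T(0, 1, 1/3): density 6x below the mode 1/3 and 3(1−x) above),
T ~ Bernoulli(½), and Y = α(X) + θ(X)·T + ε with ε ~ N(0, 1). Shapes:
linear θ(x) = β(x−0.5); concave β(0.3 − 0.9(x−1)²); convex
β(−0.3 + 0.9x²). β is a unitless effect-size scale (error SD 1); the
standard grid is {0.4, 0.6, 0.8, 1.0, 1.2}, with β = 0.8 the "clinically
relevant" anchor at which a quarter of linear/uniform patients have
θ > 0.2. The four standard scenarios pair these as
(linear, uniform), (linear, triangular), (concave, uniform),
(convex, uniform); bounded marker support is required by the
simultaneous-band theory, so normal markers are out of scope. α ≡ 0 in
generation without loss: treatment-block estimates of a correctly
specified analysis model are invariant under Y′ = Y + a(X) (tested). The
error SD is settable purely as a test hook for exact-recovery checks.

What the generator does *not* emulate about real trials: covariate
measurement error, non-normal or heteroscedastic outcomes, informative
dropout, model misspecification beyond the polynomial family (a wrong
degree can be forced via the `degree` option, but the standard
configuration pairs each shape with its correct model). Passing tests
therefore certify the behaviour of the construction principles under a
correctly specified polynomial world, not their robustness.

## Study engine

Default study: n = 1500 per trial (chosen so the most conservative rule,
SIM, has ≥ 90% power in the linear/uniform world at β = 0.8) and 2500
replicates (power estimated to SE ≈ 0.6 points at 90%). Per replicate:
sample, fit, pretest, construct all four rules at the configured
level(s), integrate the quality measures. Aggregates are means over
replicates with Monte Carlo standard errors (binomial √(p(1−p)/R) for
power and inclusion probabilities). Common random numbers throughout:
rules share the trial within a replicate, and confidence levels of a
(1−γ) sweep share replicate streams, so EST is exactly constant across
levels and comparisons are paired. Replicate streams are spawned from
the master seed with counter-based SeedSequence keys (cell, replicate,
redraw), so results are independent of execution order and extending the
replicate count leaves earlier replicates unchanged. Singular fits are
redrawn and counted (essentially impossible at n = 1500); degenerate
roots are counted in the diagnostics. The bundled test suite runs cells of
1000–2000 replicates (Monte Carlo SEs of at most ~1.6 points on
proportions) as a deliberate size/precision trade-off; the reproduction
script uses 1000-replicate cells except for the linear/uniform cell,
which gets 20 000 replicates because it measures an inclusion
probability of about 2.5% and a binomial SE near 0.1 points is needed
for that estimate to be informative. The engine default remains 2500.

## Known limitations

* The delta-method root interval is first-order only; for the linear
  model (ratio root) it can be poor in small samples. Fieller-type or
  bootstrap intervals are intentionally out of scope.
* Sup-t calibration is Monte Carlo and grid based; with the default grid
  the boundary error of the simultaneous band is far below the
  replicate-to-replicate noise but not exactly zero.
* Only the zero threshold is implemented; rules of the form θ̂(x) > c for
  a clinical-relevance margin c, non-polynomial effect estimators, and
  survival/binary outcomes are out of scope.
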