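# Methods

## Model

powerep analyzes a pair of studies — one original, one replication — on the
standard meta-analytic normal approximation: each study i ∈ {o, r} reports an
effect estimate θ̂ᵢ with likelihood N(θ, σᵢ²) and known standard error σᵢ.
Effect sizes are generic reals on a single scale (standardized mean
differences by default); effect measures that need a transformation for
normality (odds ratios, correlations) are transformed by the caller before
entry. Standard errors are treated as known constants; no degrees-of-freedom
corrections are applied.

The original study enters the analysis through a *normalized power prior*:
updating a flat initial prior by the original likelihood raised to the power
α ∈ [0, 1] gives θ | α ~ N(θ̂ₒ, σₒ²/α). α = 1 pools the two studies
completely, α = 0 discards the original data. α itself is either fixed,
estimated by empirical Bayes (the closed form min{1, σₒ²/(d² − σᵣ²)} for
d² > σᵣ² + σₒ², else 1, with d = θ̂ᵣ − θ̂ₒ), or given a Beta(x, y) prior —
uniform Be(1, 1) by default. α is hard-restricted to [0, 1]; the
relative-precision extension α > 1 is rejected with an explicit error, since
it would claim more information than the original study supplied. The
improper flat prior's arbitrary constant is fixed to 1; it cancels wherever
it appears.

### Estimation

With a Beta(x, y) prior on α, the joint posterior of (α, θ) is available up
to the normalizing constant

m(θ̂ᵣ) = ∫₀¹ N(θ̂ᵣ | θ̂ₒ, σᵣ² + σₒ²/α) Be(α | x, y) dα,

computed by adaptive Gauss–Kronrod quadrature. The α marginal is this
integrand normalized; the θ marginal has a closed form proportional to
N(θ̂ᵣ | θ, σᵣ²) · M{x + ½, x + y + ½, −(θ̂ₒ − θ)²/(2σₒ²)} with M Kummer's
confluent hypergeometric function. Both marginals are tabulated on grids
(default 2001 points; α on (0, 1], θ spanning the union of the isolated
replication posterior and the fully pooled posterior, each ± 8 sd, so that
conflict-inflated posteriors are never truncated). Modes are refined by
bounded scalar optimization within one grid cell of the grid argmax;
posterior means use the trapezoid rule (no analytic mean is attempted for
the α marginal).

Highest-posterior-density intervals come from a water-level bisection on the
tabulated density: the threshold is bisected until the region
{density ≥ threshold} carries the requested mass (tolerance 1e−4 in mass),
with region endpoints linearly interpolated between grid points and ties
resolved toward the shorter interval. If the optimal region touches a domain
boundary the interval attaches to it; a disconnected region (possible for
multimodal densities) is reported as its enclosing hull.

Two estimation facts shape interpretation. First, for perfectly agreeing
studies the α posterior does not concentrate as σᵣ → 0: it converges to
Be(x + ½, y) — Be(3/2, 1) under the uniform prior — so the posterior
probability of, say, α > 0.8 can never exceed ≈ 0.28. Second, conflict
inflates the θ posterior variance relative to the isolated replication
analysis, but only in a moderate-conflict regime: under extreme conflict
the α posterior collapses near zero and the θ posterior reverts to the
isolated N(θ̂ᵣ, σᵣ²), so the variance is not globally monotone in the
disagreement (the tests sweep the moderate regime and separately check the
inflation beyond σᵣ²).

### Hypothesis tests

Four Bayes factors, all computed in log space so that astronomically
one-sided evidence never under- or overflows:

* **Effect tests.** BF₀₁ contrasts H₀: θ = 0 with the power-prior
  alternative, either mixed over α ~ Be(x, y) (one quadrature) or with
  α = 1 fixed, which is the replication Bayes factor under normality — a
  density ratio of two normals.
* **Compatibility tests.** BF_dc contrasts discounting with pooling.
  The *point* version (H_d: α = 0 vs H_c: α = 1) needs a proper initial
  prior; we use the unit-information prior N(0, κ²) with κ² = 2 by default
  (from Var(θ̂) ≈ 4/n for a standardized mean difference and the minimal
  n = 2), giving a ratio of normal predictive densities with shrinkage
  s = 1/(1 + σₒ²/κ²). The *partial* version (H_d: α ~ Be(1, y), default
  y = 2) avoids the initial prior entirely.

As σᵣ → 0 the effect tests are consistent (evidence accumulates without
bound for the true hypothesis) but both compatibility tests converge to
positive constants: √(1−s)·exp[−½{θᵣ²/κ² − (θᵣ − sθ̂ₒ)²/(sσₒ²)}] for the
point version and B(3/2, y)/B(1, y) · M{y, y + 3/2, (θᵣ − θ̂ₒ)²/(2σₒ²)} for
the partial one. At the Labels original (0.21 ± 0.05, κ² = 2) the most
extreme attainable values are ≈ 1/28.6 and 1/1.875. Orientation follows the
convention that values > 1 favor the numerator hypothesis; the CLI and
reports print values below one as reciprocals ("1/19").

### Design

For the point compatibility test, {BF_dc ≤ γ} is a quadratic region in the
future estimate: (θ̂ᵣ − θ̂ₒ(σᵣ² + κ²)/κ²)² ≤ X with a closed-form X. Since
θ̂ᵣ is normal under either design hypothesis (predictive N(0, σᵣ² + κ²)
under discounting, N(sθ̂ₒ, σᵣ² + sσₒ²) under compatibility), the success
probability is a non-central chi-squared CDF — validated against Monte Carlo
throughout. Negative X means the success region is empty (probability 0,
not an error). A guard rejects κ² ≤ sσₒ², although that geometry is
unreachable: sσₒ² is the harmonic mean of σₒ² and κ² and always lies below
κ². Evidence-for-discounting probabilities are complements of the same
closed form, never a second derivation.

`find_replication_se` exploits the monotonicity of the success probability
in σᵣ: the feasible set is (0, σᵣ*] and the boundary σᵣ* — the largest
adequate standard error, i.e. the smallest adequate sample size — is
returned after a log-grid scan plus Brent refinement. Because the
probability levels off at an asymptote below 1 as σᵣ → 0, unattainable
targets raise an explicit infeasibility error carrying the asymptote
estimate. Standard errors convert to total sample sizes via n = ⌈4/σᵣ²⌉
(the SMD approximation); no closed-form design exists for the effect tests,
which are designed by simulation instead. The evidence thresholds default
to γ = 1/10 (for compatibility) and 10 (for discounting) — conventional
decile labels; γ is always explicit in the API because no canonical value
exists. The exported design curve uses σₒ²/σᵣ² as "relative sample size",
the natural choice under the n ≈ 4/σ² approximation.

### Hierarchical correspondence

The two-study normal hierarchical model (θ̂ᵢ | θᵢ ~ N(θᵢ, σᵢ²),
θᵢ | θ⋆ ~ N(θ⋆, τ²), flat prior on θ⋆) matches the power-prior analysis
exactly. For fixed parameters the replication-effect posteriors coincide iff
α = σₒ²/(2τ² + σₒ²), equivalently τ² = (1/α − 1)σₒ²/2, and on the relative
scale α = (1 − I²)/(1 + I²) with I² = τ²/(τ² + σₒ²) — an involution. For
random parameters, a Beta(x, y) prior on α corresponds to the
change-of-variables density f(τ²) = Be(σₒ²/(2τ² + σₒ²) | x, y) ·
2σₒ²/(2τ² + σₒ²)², a generalized F law on τ², and to
f(I²) = Be((1 − I²)/(1 + I²) | x, y) · 2/(1 + I²)² on I², a generalized
beta law free of σₒ. The generalized-F scale convention is ambiguous in the
field's notation (it appears both as scale 2/σₒ² and σₒ²/2 depending on the
parameterization direction); this package therefore defines the matched
prior *constructively* by the change of variables above and reports the GF
label with scale tied to σₒ²/2 — both notations name the same density.

The three Bayes factors are recovered as hierarchical marginal-likelihood
ratios: the effect test from θ⋆ = 0, τ² = 0 against
θ⋆ | τ² ~ N(θ̂ₒ, σₒ² + τ²) with the matched τ² prior; the point
compatibility test from the two fixed-effects (τ² = 0) unit-information
priors; the partial test from the matched GF prior against τ² = 0. The
θ⋆ layer always integrates analytically (normal–normal); the τ² layer by
quadrature under the substitution u = τ²/(τ² + σₒ²), with prior quantiles
inserted as break points so concentrated priors are resolved.

The correspondence also explains the compatibility tests' inconsistency:
a beta prior on α is a prior on *relative* heterogeneity, entangled with
σₒ². An inverse-gamma prior IG(q, r) on τ² breaks the entanglement and
yields a consistent test; on the α scale it implies the density
f(α) ∝ α^{q−1}(1 − α)^{−(q+1)} exp{−2rα/(σₒ²(1 − α))}, which piles up near
α = 0 as σₒ shrinks. α = 0 / τ² = ∞ endpoints are represented by explicit
markers, never floating-point infinities inside densities.

## Numerical choices

* α-quadrature: adaptive Gauss–Kronrod with pure relative control
  (epsrel 1e−8, epsabs 0), split at 1e−4 with the substitution u = √α on
  the lower piece (the integrand vanishes like √α at the origin). Beta
  priors with a shape above 50 get quantile break points; shapes below 0.1
  switch to integrating against the beta CDF (α = F⁻¹(p)), which resolves
  priors whose mass hugs an endpoint within e^(−1/shape). Non-convergence
  raises an error carrying the achieved tolerance.
* Confluent hypergeometric: `hyp1f1` after the Kummer transformation
  M(a, b, −z) = e^(−z) M(b − a, b, z) for negative arguments; for |z| > 700
  the integral representation is evaluated in log space.
* Seeding: one integer seed per simulation; substreams for the original,
  replication and hierarchical layers are spawned via `SeedSequence`, so
  adding studies never perturbs earlier draws and equal seeds give
  byte-identical output.

## Synthetic data

The generator mirrors the model the analysis assumes — normal estimates
around fixed or hierarchically drawn true effects, default conditions
matching the Labels original (effect 0.21, SE 0.05, compatible replication
of equal SE). It deliberately omits the ways real replication data depart
from that model: questionable research practices and publication bias
inflating the original estimate, non-normal likelihoods at small sample
sizes, and unknown (estimated) standard errors. Passing recovery tests
therefore demonstrate internal calibration of the machinery, not robustness
to those violations.

Monte-Carlo oracle checks use 1e5 draws; recovery reports use 500–1000
simulations with an 801-point grid (about three seconds per thousand
simulations), the problem sizes used throughout the test suite. Under the
compatible truth the uniform-α analysis is mildly conservative: only the
fixed-α = 1 posterior is exactly calibrated, and mixing over α widens the
interval, so the measured 95% HPD coverage sits near 0.97 (measured
0.9705 ± 0.003 over 4000 simulations) rather than 0.95.

## Reference-value caveats

The built-in Labels dataset stores the published two-decimal summaries.
The published table and intervals were evidently computed from unrounded
source data: recomputation from the printed inputs reproduces some entries
only approximately (e.g. the third replication's complete-discounting Bayes
factor recomputes to ≈ 28 where 16 is printed, and its θ interval to
(0.334, 0.499) where (0.31, 0.5) is printed). Robust quantities — the rep-2
compatibility Bayes factor, the limiting Bayes factors, the Be(3/2, 1) tail
probabilities, the α-posterior modes and the rep-2 α-HPD lower endpoint —
are checked within 5% (or at the printed precision, e.g. the rep-1 mode,
whose exact value 0.2101 sits 5.04% from the one-decimal print 0.2); the
remaining table entries are checked by sign and ordering only. Two source
discrepancies are resolved as follows: the replication standard errors
follow the published table (rep 2: 0.06, rep 3: 0.04) where the prose swaps
them, and the rep-3 α interval is reported as computed (the density
vanishes at α = 0; the published lower endpoint 0 appears to be rounded).

## Limitations

Exactly one original and one replication study; multisite joint modeling,
robust mixture priors, exact t/binomial likelihoods and α > 1 are out of
scope. All inference is grid/quadrature-based — no MCMC — which is exact to
the stated tolerances for this two-study setting but does not generalize to
higher-dimensional extensions. Frequentist operating characteristics beyond
the recovery checks above are not studied.
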