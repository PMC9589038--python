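# Methods

## Model and assumptions

The unit of analysis is a panel of `m` *nearly independent* SNPs — the
effective number of independent tests genome-wide after LD pruning or
clumping (default `m = 60,000`, appropriate for European-ancestry panels at
conventional clumping thresholds; with ~4.5M genotyped/imputed SNPs each
independent SNP stands for roughly 75 correlated ones).  Effects are
*standardized*: the regression coefficient `β` of the standardized phenotype
(or disease liability) on the standardized genotype.  `β` is assumed
independent of allele frequency, which makes per-allele effects implicitly
inversely related to SNP variance; frequency-dependent architectures are out
of scope.

Across SNPs, effects follow a point-normal mixture: mass `π₀` exactly at
zero, the remainder `N(0, σ²)` with `σ² = h²/(m(1−π₀))` so the causal SNPs
jointly account for the SNP heritability `h²`.  `π₀ = 0` recovers the
infinitesimal model.  `π₀ = 1` is rejected wherever `σ²` is needed (0/0);
the outcome formulas accept it as a pure-null run with mean power pinned to
zero.

The effect estimate from a random quantitative sample of size `n` is
`β̂ | β ~ N(β, 1/n)` — the sampling variance is fixed at exactly `1/n`
(standardized data; no residual-variance correction for large effects), so
marginally

```
β̂ ~ π₀·N(0, 1/n) + (1 − π₀)·N(0, σ² + 1/n).
```

For binary traits, analysis runs on the liability scale of the threshold
model: a standardized log-odds ratio `γ` converts to a liability effect via
`β ≈ K(1−K)/φ(Φ⁻¹(K)) · γ` at prevalence `K`.

## Power distribution

The two-sided single-SNP test is a 1-df chi-square with noncentrality `nβ²`;
power at level `α` is evaluated in the equivalent normal form
`Q(c − √n|β|) + Q(c + √n|β|)`, `c = Φ⁻¹(1 − α/2)`, which keeps full relative
accuracy when power is itself at the `1e-8` scale (the `ncx2` route loses
precision there; the two agree to 1e-9 relative at moderate levels, which
the tests assert).

Since causal `β` is random, power is a random variable across causal SNPs.
Its law is discretized on `[−10σ, +10σ]` split into `grid_points = 8193`
equal intervals: interval probability mass (renormalized; the range carries
all but ~1e-23 of the law) attached to power at the interval midpoint.
Numerical choices:

- 8193 points makes doubling the grid move tabulated moments by < 1e-6.
- The computation is performed on the standardized scale `z = β/σ`, making
  the moments a pure function of `(nσ², α, grid_points)`; architectures
  matched on `nσ²` give identical results, which is asserted bitwise for
  exactly-representable matches.
- The odd interval count places one midpoint exactly at `β = 0`, whose power
  is `α` at any `n`.  Mean power therefore saturates at `1 − mass₀(1−α)`
  with `mass₀ ≈ 1e-3`, not exactly 1; limits in tests allow for this
  discretization floor.

`E(p)` rises with `n` and `σ²` and the implied power density is strongly
bimodal at intermediate `n` (floor/ceiling effects): most causal SNPs are
nearly undetectable or nearly certain discoveries.

## Discovery counts

Each SNP's significance is a Bernoulli trial (rate `α` for null SNPs, `p_j`
for causal), so the count `S` is Poisson-binomial:

```
E(S)   = m[π₀α + (1−π₀)E(p)],          E(C) = m(1−π₀)E(p)
Var(S) = mπ₀α(1−α) + m(1−π₀)[E(p)(1−E(p)) − Var(p)]
```

Probability intervals are normal approximations `mean ± z₀.₉₇₅·sd`, floored
at zero, without continuity correction.

**Variance semantics.** `Var(S)` subtracts `Var(p)`: it is the sampling
variance of a *repeated GWAS of one fixed trait* (effect sizes realized
once), averaged over architecture realizations.  Re-running the whole
generative process (fresh causal sets and effects each replicate) produces a
larger dispersion.  The simulator exposes both regimes via
`SimConfig.redraw_effects`; the fixed-trait regime is the one `Var(S)`
describes and the one used for variance validation.

## Variance explained

With threshold `T = Φ⁻¹(1 − α/2)/√n` on the `β̂` scale, the *apparent*
variance explained is `E(S) · E(β̂² | |β̂| > T)`, the conditional second
moment taken over the full two-component estimate mixture — null false
positives contribute through their (tiny) truncated second moment.  All
truncated moments use closed zero-mean truncated-normal forms assembled from
*unconditional* tail moments (`E[X²·1{|X|>t}] = v(2zφ(z) + erfc(z/√2))`,
`z = t/√v`), with `φ(z)/Q(z)` ratios avoided entirely so nothing underflows
at thresholds tens of sd out.

The *corrected* variance explained replaces `β̂²` by the posterior second
moment under the point-normal prior: with `λ = σ²/(σ² + 1/n)`,

```
E(β²|β̂) = P(causal|β̂)·(λ²β̂² + λ/n),
```

`P(causal|β̂)` by Bayes between the two mixture components (computed from
log-density ratios through a logistic for numerical stability).  Averaging
over the significance-truncated mixture has a closed form, because
`P(causal|β̂)` times the mixture density is just the causal component
density: the correction reduces to `m(1−π₀)[λ²·TM₂(v₁,T) + (λ/n)·TP(v₁,T)]`.
The test suite cross-checks it against direct quadrature to 1e-8 relative.
One published presentation squares the posterior second moment inside the
sum; that is dimensionally inconsistent for a variance proportion and this
package sums it unsquared, which also reproduces the published worked
values.

The variance of the apparent variance explained uses the law of total
variance with per-SNP contributions treated as conditionally i.i.d. given
`S`: `Var = E(S)·Var(β̂²|sig) + Var(S)·E(β̂²|sig)²`.  This is an
approximation: it exceeds the fixed-trait sampling variance (where each
significant SNP's `β̂²` varies only by estimation noise around its fixed
`β²`) and falls short of the fully marginal variance across trait
realizations.  The tests assert exactly that bracketing rather than
pretending either regime is matched.

## Study designs and equivalent sample size

A design is summarized by the random-quantitative-sample size `n*` with the
same sampling variance for the liability/trait-scale estimate:

- **Case-control** (`K`, case fraction `w`):
  `n* = n·w(1−w)φ²(Φ⁻¹(K))/(K²(1−K)²)`, the reciprocal of the liability
  effect's sampling-variance inflation.  Balanced sampling of a rare disease
  concentrates extreme liabilities, so `n*` can exceed `n`.  The factor is
  maximized at `w = 1/2` for every `K`, and the direction of the rescaling
  is validated end-to-end by case-control simulation.
- **Extreme-phenotype selection** (tails `Y < tl`, `Y > tu`, lower-tail
  sample share `pl`): the selected trait variance `Var(Y_S)` follows from
  the law of total variance over the two truncated tails.  The published
  conversion is `n* = n·Var(Y_S)²`; a first-order analysis of the
  selected-sample regression (selection on `Y` leaves `E(x|y)` intact, so
  the in-sample slope is `β·Var(Y_S)` with residual variance `≈ Var(Y_S)`)
  gives noncentrality `nβ²·Var(Y_S)`, i.e. `n* = n·Var(Y_S)`, and forward
  simulation decisively supports the first-order form (empirical
  noncentrality 21.7 vs 22.0 predicted by `nV`, vs 96.5 by `nV²`, at
  `V = 4.39`).  `equivalent_n_extreme` defaults to the published squared
  formula for compatibility and exposes `squared=False` for the
  simulation-supported scaling; the simulator's validation path uses the
  latter.  This disagreement is surfaced, not silently patched.
- **Meta-analysis**: equivalent sizes add across component studies.

## Polygenic scores

Score efficacy is `r²(G, G̃) = Cov²(β, β̃)/(Var(β)Var(β̃))` over the joint
law of true effects (point-normal across all `m` SNPs, nulls included, so
`Var(β) = h²/m`) and estimates.  OLSE weights give the closed form
`1/(1 + m/(nh²))`, independent of `π₀`.  Hard thresholding
(`β̃ = β̂·1{|β̂|>T}`) has closed truncated-moment covariances; the optimal
`T` comes from a bounded scalar minimization on `[0, 10√(σ²+1/n)]` and is
reported with its equivalent two-sided p-value.  Posterior-mean weights use
`r² = Var(β̃)/Var(β)` (projection identity) with `Var(β̃)` by adaptive
quadrature (relative tolerance 1e-10) over the estimate mixture; at `π₀ = 0`
this collapses to the linear-shrinkage closed form `r² = λ`, asserted in
tests.  The ordering posterior ≥ optimal threshold ≥ OLSE holds at every
tested grid point.

Liability-scale `r²` converts to ROC AUC exactly under the threshold model:
with `G = r²L + u`, the concordance probability
`AUC = E[Φ(a(L₁−L₂))]`, `a = √(r²/(2(1−r²)))`, over independent case
(upper-tail) and control (lower-tail) truncated liabilities, evaluated by
200-node Gauss-Legendre quadrature in probability space.  Unlike the common
normal-approximation formula, this is accurate over the whole range,
including `r² → 1 ⇒ AUC → 1`, and matches simulation within 0.005.

## Inverse solvers

`solve_n_for_detection` brackets `E(p)(n) = fraction` on `log n` (strict
monotonicity) with Brent's method; "detect X%" means mean causal power,
excluding the `α` term, so `E(C) = X%·m₁` at the solution.  Solutions scale
exactly as `1/σ²`.

`solve_pi0_range` finds `{π₀ : S_reported inside the 95% interval of S}`.
`E(S)` is *unimodal* in `π₀` (the causal count falls while per-SNP power
rises), so a reported count below the peak has two disjoint preimage
ranges; the solver seeds coverage with both covered grid points and
root-found `E(S) = S` crossings (catching windows narrower than the scan
step), refuses to guess between disjoint ranges (asking for a narrower
`bracket`), and refines the edges of the unique range by bisection to 1e-6.

## Simulator

Genotypes are `Binomial(2, f)`, `f ~ Uniform(0.01, 0.5)`, sample-
standardized per SNP (population standardization would differ at `O(1/n)`);
phenotype is the causal sum plus `N(0, 1−h²)` noise.  Association uses the
closed-form slope `x·y/n` on standardized data — identical to per-SNP OLS
because `Σx² = n` — with Wald chi-square `nβ̂²`.  Case-control sampling
thresholds the liability at `Φ⁻¹(1−K)`, oversamples cases to fraction `w`,
and tests each SNP with the logistic score statistic
`U²/(ȳ(1−ȳ)Σx²)`, mapping the one-step log-odds estimate `U/V` to the
liability scale.  Extreme selection keeps tail individuals until the quota
fills and maps in-sample slopes back to the population trait scale through
`Var(Y_S)`.

Reproducibility: replicate `i` uses the `i`-th spawned child of the seed
sequence; the quantitative path streams SNP chunks with per-chunk
substreams, so cached and regenerated chunks are bit-identical (asserted in
tests).  Genotypes are float32 for speed; estimates are accumulated in
float64.

Validation runs at reduced scale: the analytic/empirical agreement checks
use `m = 2,000` panels, and the 100-replicate coverage reproduction uses
`m = 10,000` with four sample sizes chosen to span the rising part of the
discovery curve at matched `nσ²` — the moments provably depend on the
architecture only through `nσ²`, so the scaling preserves the per-SNP power
regime while keeping the suite's runtime in minutes.

## What the synthetic data does and does not emulate

The generator realizes exactly the model's assumptions: independent SNPs,
frequency-independent standardized effects, Gaussian residuals, exact `1/n`
sampling variance (asymptotically).  It does not emulate LD (so `m` is an
*effective* count whose right value is itself uncertain), rare variants
(MAF < 1%), frequency-dependent selection signatures, covariates,
relatedness, population structure, or cross-cohort heterogeneity in
meta-analyses.  Passing tests therefore certify the mathematics of the
calculator, not the adequacy of the point-normal model for any particular
trait — published applications show real traits (height, schizophrenia) can
deviate from it.

## Known limitations

- Forward predictions are sensitive to `π₀` near its extremes: around the
  published four-trait settings, moving `π₀` by 0.005 (its printed rounding
  radius) moves `E(S)` by 1–5%.  Exact reproduction of published point
  predictions requires the unrounded fitted `π₀`, not the two-decimal
  values tables print.
- The `Var(VE)` formula is an approximation (see variance semantics above).
- The published `n·Var(Y_S)²` extreme-selection conversion disagrees with
  simulation; both forms are exposed.
- One published required-sample-size table cell (`h²=0.5`, `π₀=0.99`, 50%
  detection) appears to carry an exponent typo (prints 7.72e5 where the
  scaling structure and this implementation give 7.72e4).
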