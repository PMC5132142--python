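# Methods

## Model and statistic

Let `G` be the n × p matrix of additively coded genotypes (allele counts
0/1/2), `Y` a binary phenotype with `d` cases, and optionally `C` an n × k
covariate matrix. Partition the rows of `G` by phenotype and let `S¹` and
`S⁰` be the Pearson correlation matrices of the case and control rows
(partial correlations given the covariates when k > 0). Each off-diagonal
entry estimates the genotypic LD measure Δ̂ between a marker pair within
that subpopulation.

The global null is equality of the two population correlation matrices,
`H₀: P¹ = P⁰`. A pairwise interaction on the log-odds scale,

    logit P(Y=1 | G) = β₀ + Σᵢ βᵢ Gᵢ + Σ₍ᵢⱼ₎ βᵢⱼ Gᵢ Gⱼ,

makes case status depend on marker products, so conditioning on Y distorts
within-class LD and violates `H₀`; purely marginal effects shift class-wise
means but leave within-class correlations essentially intact (verified
empirically by the calibration study below). Marker correlation in the
source population affects both classes equally and does not violate `H₀` —
the property that makes this test robust where case-only methods fail.

The statistic is the greatest root of the two-matrix pencil

    λ₁ = λ_max( (d S¹ + (n−d) S⁰)⁻¹ · d S¹ ),

with the case-weighted matrix in the numerator. The choice of numerator is
a genuine design decision: the two one-sided greatest-root tests (case- or
control-weighted numerator) share the same null law in balanced designs but
are different tests, and in case-control sampling the interaction signal
loads on the direction in which the *case* correlation structure exceeds
the pooled structure. Monte-Carlo power under the simulators below is
roughly 0.25–0.30 higher for the case-weighted form at n/p = 80 with no
measurable difference in null behaviour, so the case-weighted form is the
implemented test.

Johnstone's Tracy–Widom approximation for the greatest root of a
double-Wishart (Jacobi) problem gives the null reference: with
`s = n₁ + n₂ − 1`, angles

    sin²(γ/2) = (min(p, n₂) − ½) / s,    sin²(φ/2) = (max(p, n₂) − ½) / s,

centering `μ = 2 log tan((φ+γ)/2)` and scaling
`σ³ = 16 / s² / (sin²(φ+γ) sin φ sin γ)`,

    T = (logit λ₁ − μ) / σ  →  F₁   (Tracy–Widom, order 1),

where the numerator sample takes the `n₂` role: `n₂ = d`, `n₁ = n − d`.
The roles of n₁ and n₂ are not exchangeable (they coincide when d = n − d);
this assignment is asymmetric by construction and relabeling cases and
controls changes the test. The p-value is `1 − F₁(T)`.

## Tracy–Widom law of order 1

F₁ is evaluated from a shipped 2,101-point table on [−13, 8] (step 0.01)
with monotone PCHIP interpolation, clamped to 0/1 outside the grid (tail
mass there < 1e-8). The table is generated by solving the Painlevé II
equation `q'' = xq + 2q³` for the Hastings–McLeod solution (`q ~ Ai(x)` on
the right, `q ~ √(−x/2)` on the left) as a two-point boundary value problem
(`scipy.integrate.solve_bvp`, tolerance 1e-12), then evaluating

    F₁(s) = exp( −½ ∫ₛ^∞ [ q + (x−s) q² ] dx )

by spline antiderivatives, with the Airy tail beyond the grid added by
quadrature. The table reproduces the literature values of the F₁ mean
(−1.20653), standard deviation (1.26800) and upper percentiles (0.4501 /
0.9793 / 2.0234 at 0.90 / 0.95 / 0.99) and agrees to ≤ 1e-4 with an
independent shooting integration in the test suite. Interpolation error at
step 0.01 is orders of magnitude below the 1e-4 accuracy contract.
`epiget tw-table` regenerates the table (≈ 2 s). Only order 1 (the
orthogonal ensemble) is implemented.

## Numerical choices

- λ₁ is computed as the symmetric generalized eigenproblem
  `d S¹ v = λ (d S¹ + (n−d) S⁰) v` via Cholesky reduction
  (`scipy.linalg.eigh`), never by explicit inversion; a singular weighted
  sum raises a rank error suggesting marker filtering.
- λ₁ is clamped to [1e-12, 1 − 1e-12] before the logit.
- Markers are mean-centered and standardized *within each partition*
  (partition-specific moments). This matters under strong marginal effects,
  where whole-sample centering would leak mean shifts into correlations.
- Covariate adjustment residualizes each marker on [1, C] by least squares
  within each partition and correlates the residuals; no degrees-of-freedom
  correction for k is applied to the correlation estimates.
- A marker with zero variance within a partition is a hard error naming the
  marker; `drop_degenerate=True` (CLI `--drop-degenerate`) drops it from
  both matrices with a warning — dropping changes p and hence μ/σ, so it is
  never silent.
- The pencil weights use d and n−d (not d−1, n−d−1); the correlation
  estimates themselves are scale-free so the distinction only enters the
  weights, where it is negligible at the sample sizes of interest.
- Fits warn (not fail) when n/p < 5, the regime where the Tracy–Widom
  approximation degrades, and when p > min(d, n−d).

## Benchmark two-stage test

For each ordered marker pair (i < j by column order) the case-only trend
test regresses `Gᵢ` on `[1, C, Gⱼ]` over the case rows and Wald-tests the
`Gⱼ` slope with a t reference on d − k − 2 degrees of freedom. With no
covariates this t equals the Pearson-correlation t among cases and is
symmetric in the pair (the slope estimate is not, but its p-value is), so
the global path computes all p(p−1)/2 p-values from one case correlation
matrix. Fisher's method combines them: `X = −2 Σ log pᵢ ~ χ²(2m)` under
independence. P-values underflowing to 0 are floored at 1e-300 with a
warning. The method is valid only for markers uncorrelated in the source
population; under correlation the pair p-values are anticonservative and
dependent, and the combined test rejects essentially always — retained
deliberately as the comparison baseline.

## Simulators

`simulate_genotypes` draws SNPs as Binomial(2, MAF) allele counts coupled
by an exchangeable Gaussian copula: latent rows share one common factor
with loading √ρ, are mapped through the standard normal CDF and then the
Binomial(2, MAF) quantile. Discretization attenuates the latent correlation
— at MAF 0.25, latent ρ = 0.1 yields genotype correlation ≈ 0.071 (factor
[φ(z₀)+φ(z₁)]²/Var(G) ≈ 0.713) — the attenuated value is the one that
matters for, and is reproduced in, the correlation-contrast example. MAF
is either fixed or drawn per SNP from a uniform range, once per data set
(fresh each replicate); a "MAF" above 0.5 is taken literally as the allele
frequency.

`simulate_case_control` emulates cohort-to-case-control sampling: subjects
are generated in blocks of 10·n (one MAF draw per data set) until both
class quotas are met, capped at 100·n subjects, then the requested cases
and controls are subsampled uniformly without replacement and shuffled.
For iid subjects this is distributionally identical to materializing one
large pool first. Hitting the cap raises an error reporting the achieved
prevalence.

`simulate_disease` composes known risk SNPs (MAF, odds ratio), binary or
normal environmental exposures (returned as covariates), unassociated null
SNPs, and optional G×G product terms on the risk SNPs, all mutually
independent, under a logistic outcome model. It is a configurable
architecture generator; no specific disease's published parameter set is
bundled.

What the simulators do *not* emulate: LD-block/haplotype structure (the
copula correlation is exchangeable, not genomic), Hardy–Weinberg
disequilibrium, genotyping error and missingness, G×E interactions, or
population stratification. Passing tests therefore demonstrate calibration
and power under clean HWE-consistent sampling, not robustness to those
real-data features.

## Experiment harness and study designs

The packaged grids mirror the evaluation studies:

- **Type-I grid** (20 cells): n ∈ {250, 500, 1000, 2000, 4000} × ρ ∈
  {0, 0.1} × {no effects (β₀ = −5), marginal effects (β₀ = −2, log(1.15) on
  SNPs 1–10)}; p = 50, MAF ~ U(0.25, 0.75), balanced n/2 : n/2 subsampling,
  no interactions.
- **Power grid** (15 cells, ρ = 0): model 1 (β₀ = −3, marginals on SNPs
  1–10, five interaction pairs at log 2 drawn among the main-effect SNPs),
  model 2 (as model 1 with pairs among SNPs 11–50), model 3 (β₀ = −1, no
  marginals, pairs among all 50). Pairs are redrawn each replicate.
- **Correlation-contrast example**: 20 replicates of a five-SNP panel
  (MAF 0.25, ρ = 0.1) with marginal log(1.5) effects on SNPs 1–2 and a
  log(3) interaction between them, 500/500 sampling; reports the averaged
  S¹ and S⁰ and the case/control correlation gap at the interacting pair
  (≈ 0.31) versus background pairs (≈ 0.02). With a positive interaction
  the case correlation is pushed *up* and the control correlation *down*.
- **Calibration study**: two collections of null data sets (n = 500,
  p = 100, MAF 0.25, independent SNPs, 250/250 subsampling): one with no
  genetic effects and one with log(1.5) marginal effects on five SNPs
  (β₀ = −1 in both; the intercept and effect size here are this package's
  choices for the design). The empirical distribution of T is compared to
  F₁; the tail rate at the F₁ 0.95-quantile sits at or below 0.05
  (conservative) in both collections.

Replicate seeding uses `SeedSequence(master, spawn_key=(cell, rep,
attempt))`, so reports are bit-identical for a fixed master seed, invariant
to execution order and parallelism (joblib), and a single cell re-run alone
reproduces its in-grid values. Replicates failing on degenerate draws are
retried with the next attempt index up to 3 times, then counted as failures
and excluded from rate denominators. Rates carry binomial MC standard
errors √(r(1−r)/reps). The default 1,000 replicates per cell match the
full studies; the test suite uses 250-replicate scaled-down cells with
acceptance bands widened to ±3 MC-SE at the count used.

## Screening

`marginal_filter` ranks markers by the Wald p-value of the marker
coefficient in a one-marker logistic (binary phenotype) or linear
(continuous) regression including any covariates, and keeps the k best
(ties broken by input order; non-convergent/separated logistic fits get
p = 1 with a warning). Marginal association is asymptotically independent
of interaction statistics under the null, which is what qualifies it as a
screen before interaction testing; the package asserts the operational
contract only, not the asymptotic claim. `bh_fdr` exposes
Benjamini–Hochberg step-up q-values (statsmodels backend, verified against
an explicit step-up oracle in the tests). Hierarchical FDR across
global-then-local test families is out of scope.

## Known limitations

- The Tracy–Widom null is asymptotic; for n/p < 5 the approximation
  degrades (the fit warns) and below n/p ≈ 3 it can turn anticonservative.
- The test is one-sided in the spectrum (case-weighted greatest root);
  alternatives whose signature is a *smaller* extreme case eigenvalue load
  on the opposite tail and are better caught by relabeling the classes.
- A significant global result does not localize the interacting pair.
- Continuous phenotypes must be dichotomized upstream; information loss
  from dichotomization is not modeled.
- Covariate adjustment is linear residualization; strongly nonlinear
  confounding is not removed.
- The conservativeness of the null (rejection rates ~0.015–0.04 at nominal
  0.05) costs some power at small n/p.
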