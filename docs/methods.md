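# Methods

## The procedure under study

The simulator models the optional-stopping strategy as literally
practiced: draw one observation per group, test, stop at the first
p < α. Formally, with per-group samples growing one observation at a
time,

* group A: x₁, x₂, … iid Normal(0, σ²)
* group B: y₁, y₂, … iid Normal(δ, σ²)

and at every per-group size n from `n_start` to `n_max` the classical
pooled-variance Student t-statistic

    t_n = (x̄ − ȳ) / √(s_p² · 2/n),   s_p² = (s_x² + s_y²)/2,   df = 2n − 2

is compared two-sided against α. The recorded outcome per replicate is
the *first crossing* — the smallest n with p < α (strict inequality) —
plus Cohen's d at that n and at the cap. The trajectory is always
computed to `n_max` so that re-crossings back above α remain observable.

Defaults (`SequentialConfig`): `n_start=2` (the smallest n for which a
within-group variance exists), `n_max=150`, `alpha=0.05`, `delta=0`
(null), `sigma=1`, `reps=10_000`. These are the canonical study
conditions of the package; the false-positive curve they produce rises
above 0.25 by a cap of 25 per group and above 0.40 by 150.

Assumptions baked in: normal data, equal group sizes at every step,
equal variances, two-sided testing. Student rather than Welch is the
appropriate test under these conditions; Welch, unequal allocation and
non-normal data are deliberately out of scope.

## Streaming sufficient statistics

`GroupAccumulator` keeps (n, mean, M2) with Welford's update, exposing
the textbook sufficient statistics (n, Σx, Σx²) as derived properties.
Variance always comes from M2, never from Σx² − n·x̄², so the estimate
stays within ~1e-10 relative error of a two-pass computation even with a
common offset of 1e6 — the regime where the naive form loses every
significant digit. The batch simulators use the algebraically equivalent
cumulative-moment formulation (vectorized over n), with tiny negative
variances from rounding clamped to zero; the test suite pins the scalar
and vectorized paths to each other and to an independent two-pass oracle
at 1e-10.

Degenerate inputs are defined, not fatal: zero pooled variance with
equal means gives (t = 0, p = 1); with unequal means, (t = ±∞, p = 0).
p-values come from the central t-distribution via scipy (regularized
incomplete beta).

## Random-number design

A master seed feeds `numpy.random.SeedSequence`; `first_crossing_
distribution` spawns one independent substream per replicate, so results
are bit-reproducible and independent of replicate ordering. The interim
and SPRT batch simulators instead draw from a single seeded stream in
fixed-size chunks: their contract is only determinism given the seed,
and the calibration routine needs one frozen draw anyway (below). Both
designs are deterministic; they are different on purpose.

## Interim calibration

For a design with looks (n₁, …, n_L) per group, all tested at the same
level a (a Pocock-type constant boundary), the overall type-I error

    g(a) = P₀(min_j p_{n_j} < a)

is estimated by simulating the L per-look p-values for each of `reps`
null replicates **once** and reusing that matrix for every candidate a —
common random numbers. On the frozen draw, g is a non-decreasing step
function of a (steps of 1/reps), so bisection is exact: the bracket is
[0, overall_alpha] (widened multiplicatively in the single-look corner
where Monte-Carlo noise can leave g(α) just under the target) and
iteration stops when the bracketed rate gap is within `tol` (default
1e-4) or the level bracket collapses. With `reps=100_000` the returned
level for looks (50, 100) at overall 0.05 is ≈ 0.029, matching the
bivariate-normal closed-form constant (ρ = √(n₁/n₂), ≈ 0.0294) that the
test suite computes as an independent oracle. The Monte-Carlo route is
preferred over numerical integration because it calibrates the *t*-test
actually used, not a z-approximation.

Look sizes are interpreted per group throughout. Alpha-spending families
(O'Brien–Fleming, Lan–DeMets), futility bounds and conditional power are
out of scope.

## Wald's SPRT

Implemented for the simple-vs-simple normal mean with known σ. Each
observation contributes the log-likelihood-ratio increment
((θ₁−θ₀)/σ²)(x − (θ₀+θ₁)/2); the cumulative sum continues while inside
the open interval (a, b) = (log(β/(1−α)), log((1−β)/α)) and stops on
touching either bound (closed exit, Wald's convention). Runs that reach
`n_max` (default 1000) undecided are reported as `undecided_at_cap`
rather than forced to a decision. The sequential *t*-test (unknown
variance) is intentionally not implemented — it is a materially harder
procedure and outside this package's scope.

Wald's bounds are approximations: they guarantee error rates at most
α + β jointly and in practice slightly below the nominal levels, which
is what the operating-characteristic simulations show (empirical errors
~0.03 at nominal 0.05, mean stop size ≈ 7 under H1 at d = 1 versus ~13
for a matched fixed-n z-test).

## What the simulations do and do not show

The generator reproduces the idealized conditions of the procedure under
study: iid normal data, exact level-α tests, perfectly adhered-to
stopping rules. Real data add non-normality, drift, unequal variances
and missing observations, all of which change the numbers but not the
qualitative conclusions (inflation grows with the cap; calibrated looks
restore the level; the SPRT is more sample-efficient on average).
Passing tests therefore validate the procedures and their calibration
under the stated model, not robustness beyond it.

## Monte-Carlo sizes and tolerances

Stochastic checks use ±3 binomial standard errors at the configured
replicate count. Headline simulations use 10,000 replicates for the
sequential strategy (se ≈ 0.004 near a rate of 0.27) and 100,000–200,000
for interim sizes (se ≈ 0.0005–0.0007), which makes every check decisive
while keeping the full suite under a minute on one CPU. Smoke-level
structural tests use a few hundred replicates. Calibration agreement
with the printed two-look level is asserted at ±0.002, absorbing both
Monte-Carlo noise and the t-vs-z gap at n = 50/100 (below 1e-3 there).

## Known limitations

* Null and alternative distributions are normal with common known-shape
  variance; no heavy tails, no unequal allocation.
* Only constant per-look boundaries; no alpha-spending.
* SPRT requires known σ and simple hypotheses.
* The false-positive curve is exact only up to Monte-Carlo error; no
  closed-form boundary-crossing probabilities are computed.
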