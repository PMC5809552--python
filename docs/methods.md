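# Methods

## Models and estimands

Both supported models are linear with continuous mediators and outcome:
single-mediator (`Y~X`, `Y~X+M`, `M~X`) and parallel two-mediator
(`Y~X`, `Y~X+M1+M2`, `M1~X`, `M2~X`). All equations include intercepts and
are estimated by OLS; `s_X` and `s_Y` are sample SDs with an n−1 denominator.
Because the models are linear, the fitted total effect satisfies
`c = c' + Σ a_j b_j` exactly (up to floating point; the test suite asserts
1e−10), so the product-of-coefficients and difference-in-coefficients
definitions of the indirect effect coincide.

For simulation estimands the package uses closed-form population moments
under the generating model (below): `Var(Y) = (Σ a_j b_j + c')² Var(X) +
Σ b_j² + 1`, with `Var(X) = 1` (continuous) or `p(1−p)` (binary). "True"
effect sizes plug population paths and SDs into the same four formulas. The
estimator uses sample SDs while the estimand uses population SDs — the usual
estimator/estimand separation for bias and coverage.

## Data generation

`generate_dataset` draws X standard normal (continuous) or Bernoulli(p)
coded 0/1 (binary, p = 0.5 by default, mirroring a balanced two-arm trial —
the allocation ratio is a package choice since none is canonical), unit-variance
normal residuals for each mediator and for Y, independent mediator residuals,
and zero intercepts. Path-value grids correspond to zero/small/medium/large
effects in the Cohen sense: {0, 0.14, 0.39, 0.59} for the single-mediator
paths; {0, 0.101, 0.314, 0.577} with c' in {0, 0.131, 0.400, 0.740} for the
two-mediator model, restricted to a1 = b1 and a2 = b2 (256 cells).

What the generator does *not* emulate: non-normal residuals, heteroscedasticity,
correlated mediator residuals (the estimator is agnostic, the generator uses
zero covariance), measurement error, unbalanced allocation, or confounding of
the M→Y path. Passing tests therefore speak to the estimators' behaviour
under a correctly specified normal linear model, not to robustness against
those violations.

## Bootstrap intervals

Case resampling with replacement at the original n; B = 1000 by default
(configurable; no canonical value exists). Quantiles are ceiling-rule order
statistics — the ceil(q·B)-th smallest draw, no interpolation — so endpoints
are realised draws and the construction is exactly reproducible; a 1e−9
tolerance inside the ceiling guards against binary-representation spillover
(0.975·1000 must select draw 975, not 976).

The bias-corrected interval uses `z0 = Φ⁻¹(p_below)` with ties between draws
and the observed estimate counted half toward `p_below` (the verbal
"proportion exceeding" and "proportion below" conventions differ only in the
sign of z0 and give the same interval). When every draw falls on one side of
the observed estimate, `p_below` is clamped to 1/(B+1) or B/(B+1) with a
warning rather than failing.

Resamples with rank-deficient designs (constant X is the practical case for
binary X) are redrawn from the ongoing stream, with a bound of 50 rounds and
a count kept on the draws object. Undefined draws (e.g. a proportion whose
resampled total effect is exactly zero) are excluded from order statistics
and counted; an interval is reported as undefined if fewer than ceil(level·B)
defined draws remain.

## Bayesian engine

The regression equations have a-priori independent parameters and a
factorising likelihood, so each is sampled by its own two-block conjugate
Gibbs chain: the full coefficient vector jointly from its multivariate-normal
conditional (precision `X'X/σ² + τ0 I`), then the residual variance from
inverse gamma(shape0 + n/2, rate0 + RSS/2). Joint coefficient draws remove
within-equation autocorrelation, so short chains mix well. Defaults are
n_iter = 11000 with 1000 burn-in for interactive fits and 2500/500 inside the
simulation harness (these conjugate chains have effectively independent
draws, so the shorter chain trades Monte Carlo precision for throughput); a
split-chain potential-scale-reduction diagnostic is computed per fit and
non-convergent replications (R̂ > 1.1) are counted in the study output.

Effect-size draws fix `s_X`, `s_Y` at their sample values across iterations,
matching the frequentist standardizer; the alternative (per-draw
model-implied SDs) would change the estimand of the standardized measures.
Equal-tail intervals use the same order-statistic rule as the percentile
bootstrap. The HPD interval is the narrowest contiguous window of
ceil(level·ndraws) sorted draws, ties resolved toward the lowest lower
bound. Note that under this tie-break rule the HPD of *exactly* equally
spaced draws collapses to the leftmost window; for continuous posterior
draws ties have probability zero, and the invariant that is guaranteed (and
tested) is HPD width ≤ equal-tail width.

## Monte Carlo harness

Point metrics per condition × measure: bias (mean estimate − truth), relative
bias (bias/truth, undefined at truth 0, flagged when |value| > 0.05),
replicate SD (the efficiency measure), standardized bias (bias/SD). Interval
metrics: zero-exclusion rate (labelled Type I error when the true effect size
is 0, power otherwise), coverage, mean width, and imbalance defined as the
proportion of misses with the truth to the right of the interval minus the
proportion to the left. Type I error and coverage are classified against
Bradley's bands [0.025, 0.075] and [0.925, 0.975]. For the ratio mediated at
c' = 0 the truth is undefined and coverage/imbalance are reported as NA; the
proportion's truth at c' = 0 with a nonzero indirect effect is exactly 1.

Randomness: every replication draws its generator from
`SeedSequence((master_seed, condition_index, replication_index, attempt))`,
so any single cell is rerunnable in isolation and rank-deficient
replications advance `attempt` deterministically (counts reported).
Batched closed-form OLS (centered cross-product matrices solved for the
whole batch) does the heavy lifting; at n = 100 a 500-replication ×
B = 1000 bootstrap condition takes a few seconds on one CPU.

Extreme but defined proportion/ratio estimates are retained unmodified — no
trimming or winsorizing — because their instability (interval widths in the
thousands at small n) is precisely the behaviour the harness is meant to
expose.

## Replication-count choices and Monte Carlo error

The headline studies use 1000 replications per cell at full scale; the
bundled acceptance checks run 500 replications so the whole suite stays in
the minutes range. At 500 replications the binomial SE of a 0.95 coverage
estimate is ≈0.010, which the coverage check absorbs explicitly. For
relative bias the Monte Carlo SE scales with SD(estimate)/(truth·√reps); at
the smallest two-mediator cell (all paths 0.101, n = 100) this is ≈0.055 —
the same order as the 0.05 flag threshold — so the strict sub-0.05 check at
that cell is noise-dominated at 500 replications (a 50,000-replication run
puts the true relative bias of the standardized measures there at ~0.001).
This is reported as measured; thresholds and replication counts are not
adjusted around it.

## Known limitations

- No BCa (accelerated) bootstrap, studentized bootstrap, or multilevel /
  latent-variable mediation.
- No missing-data handling or robust standard errors; estimation assumes
  complete, correctly specified normal linear models.
- Priors are fixed at the diffuse defaults for the study harness;
  informative-prior elicitation is out of scope.
- The R², κ² and "maximum possible mediation" effect sizes are deliberately
  not implemented.
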