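# Methods

## Model

Counts `y_i` follow the mean-parameterised Conway–Maxwell–Poisson (MPCMP)
distribution with mean `mu_i` and dispersion `nu_i`,

    Pr(Y = y | mu, nu) = lambda(mu, nu)^y / (y!)^nu / G(lambda(mu, nu), nu),

where `lambda(mu, nu)` solves the mean constraint `E[Y] = mu` and
`G(lambda, nu) = sum_r lambda^r/(r!)^nu`.  Both components are log-linear:
`log mu_i = x1_i' beta + offset_i + theta_g(i)` and `log nu_i = x2_i' gamma`.
When the dispersion design matrix is the group indicator, `gamma` is the
vector of individual log-dispersions `alpha_i`; this is how bidispersion
(some individuals over-, some underdispersed) is expressed.  The model's
overdispersion is bounded by the geometric (`nu = 0`) limit.

### Truncation

All series are finite sums over `r = 0..k`.  Two readings are supported:
*series truncation* (`k` approximates the infinite sum; default
`k = max(60, ceil(2 mu_max))`, i.e. about twice the largest mean in play)
and a *hard support bound* (`k = y_tau` when counts genuinely cannot
exceed `y_tau`, which also makes the normalising constant exactly finite).
Truncation is part of the target density: a fit uses one `k` throughout,
so MCMC remains exact with respect to the truncated model.  Empirically,
rates solved with `k = 60` and `k = 90` agree to below 1e-8 for
`mu <= 16` and `nu >= 0.5`; the agreement degrades toward the top of the
default grid (`mu -> 32`), which is why the build ties `k` to `mu_max`.
`mu = 0` is excluded (degenerate point mass); `nu = 0` with unbounded
support is refused whenever the solved rate would reach `lambda >= 1`
(divergent geometric series) rather than silently truncated.

## Rate solvers

The CMP mean is strictly increasing in `log lambda` (its derivative is the
variance), so the mean constraint has a unique root.

* **Bracketed Newton ("bisection").**  Start from the classical
  approximation `lambda ~ (mu + (nu-1)/(2 nu))^nu`, expand a sign-changing
  bracket geometrically, then iterate Newton steps
  `t <- t + (mu - mean(t))/var(t)`, falling back to the bracket midpoint
  whenever a step leaves it.  Vectorised over arrays of `(mu, nu)` pairs
  with an active-set so converged entries stop costing.  Default tolerance:
  1e-10 on `log lambda` (relative mean error below 1e-9).
* **Polynomial roots.**  `sum_r (r - mu) lambda^r/(r!)^nu = 0` has
  coefficients negative below `mu` and positive above, hence exactly one
  sign change and (Descartes) a solitary positive real root.  Coefficients
  are assembled in log space with explicit signs, the variable is rescaled
  by the Newton starting approximation so the root sits near one, the
  largest-magnitude coefficient is normalised to one, and trailing terms
  whose contribution near the root is below 1e-40 are trimmed (they would
  otherwise underflow the leading coefficient and break the companion
  matrix).  Roots come from companion-matrix eigenvalues; the positive-real
  filter keeps `|imag| < 1e-8 (1 + |real|)`.  Cross-checks against the
  bracketed solver agree to ~2e-9 relative over `(mu, nu)` in
  `(0.1, 30) x (0.1, 5)`.
* **Look-up table.**  `log lambda` solved on a dense grid, queried by
  bilinear interpolation with the mean-axis weight computed on the
  `log mu` scale (the surface is exactly linear in `log mu` at `nu = 1`,
  so the Poisson column interpolates exactly).  Outside the grid hull the
  same bilinear form extrapolates from the nearest boundary cell, with a
  once-per-fit warning — extrapolation is a safeguard, not a recommended
  operating regime.

## The default grid

`mu` from 0.01 to 32 in steps of 0.01 (uniform on the mu scale), `nu` from
0 to 10 in steps of 0.05 — 3200 x 201 nodes, built in ~20 s on one core
by the vectorised Newton solver (bit-identical for any worker count, since
nodes are independent).  The `nu` step is a package choice: 0.05 keeps the
`nu`-direction interpolation error well below the `mu`-direction error
while keeping the table compact.  Nodes are solved to 1e-13 so that node
error is negligible against interpolation error.  Frozen oracle bounds
for this grid (1000 random interior queries): max `|log lambda|` error
below 1e-3; the induced relative error on the fitted mean stays below
~2e-3 for `nu >= 0.1` but grows as `nu -> 0`, where the mean is
hyper-sensitive to the rate.  Halving both steps cuts the maximum error
by more than 3x, consistent with the bilinear scheme's quadratic local
error.  Tables serialise to plain text with shortest round-trip `repr`
precision, so save/load is value-exact.

## Sampler

Metropolis-within-Gibbs with three update groups per iteration:

1. `beta` as one multivariate-normal random-walk block.  Starting values
   and the proposal shape come from a Poisson GLM fit (statsmodels); this
   replaces an external MPCMP maximum-likelihood fit as the initialiser
   and costs one GLM per chain.
2. `theta` (individual mean effects) as a block.  The sum-to-zero
   constraint is enforced by reparameterisation — `m - 1` free effects
   with `theta_m = -sum` — so every draw satisfies it exactly, rather
   than by post-hoc centring.
3. Each `gamma` component by a scalar normal random walk on the
   log-dispersion scale.  When the dispersion design partitions the rows
   (one indicator per individual), all components are updated in parallel
   as independent scalar Metropolis steps, which is exactly equivalent to
   sequential scans because their likelihood terms are disjoint.

Proposal scales are Robbins–Monro adapted during warmup (decay `t^-0.6`)
toward 0.234 acceptance for blocks and 0.44 for scalars, then frozen, so
retained draws satisfy detailed balance.  Repeated `(mu, nu)` pairs within
an evaluation are de-duplicated before the rate solve — factorial designs
with individual effects repeat heavily (e.g. 1600 unique pairs among
15000 observations), which is where most of the speed comes from for the
exact solvers.

A rate-solve failure during a proposal (a mean not attainable under the
truncation, or a divergent `nu = 0` series) is treated as a log-posterior
of `-inf` — the proposal is rejected with a logged warning, never a crash.
NaN in any conditional aborts with a state dump.

The per-iteration RNG consumption is fixed (proposal noise and acceptance
uniforms are drawn unconditionally), so chains with the same seed but
different rate solvers see identical proposal streams and differ only
through the lambda evaluation — the design needed for clean
solver-to-solver comparisons.

Priors are independent normals: vague `beta ~ N(0, 1e5 I)` and, for a
scalar dispersion, `log nu ~ N(0, 1e5)` by default; weakly informative
`theta ~ N(0, 0.5 log 2 I)` and `alpha_i ~ N(0, 0.25)` for individual
effects (rate doublings/halvings unlikely, equidispersion-centred).  All
are overridable in configuration.  Summaries report posterior mean, SD,
highest-density interval (shortest window over sorted draws), a Geyer
initial-positive-sequence ESS, its implied Monte-Carlo SE, and split
R-hat across chains — the latter two as convergence plumbing, not
acceptance surfaces.

## Importance diagnostic

A look-up chain targets the approximate posterior in which every rate is
the interpolated value.  For each retained draw the log importance ratio
against the exact posterior reduces to
`sum_i [ y_i d(log lambda_i) - d(log G_i) ]` (priors and factorial terms
cancel), and the approximate effective sample size is
`m_e = (sum r)^2 / sum r^2` over `K` draws: `1 <= m_e <= K`, with
equality at `K` iff the ratios are constant.  Ratios live in log space and
`m_e` is invariant to rescaling, so subtracting the max log ratio before
exponentiation is exact.  `m_e` deliberately is *not* the autocorrelation
ESS of the chain; it isolates the information lost to interpolation.
Draws whose exact-reference solve fails are dropped with a warning and
`K` reduced.  The `K` draws default to the most recent contiguous
post-warmup window, not a thinned subsample.

Timing comparisons record per-iteration wall time per solver; the
cumulative curve of a look-up chain includes the table build time, and the
crossover report gives the first iteration at which the look-up total
undercuts each alternative.  Timings are reported, never asserted — they
are hardware facts, not model properties.

## Synthetic designs

Three named designs span the regimes of interest; all counts are drawn by
CDF inversion from the exact truncated pmf at bracketed-Newton rates.

* **I** (n = 150, scalar `nu = 1.5`): ten-parameter mean model — intercept,
  five Bernoulli(0.5) indicators, one standard normal, two lognormal
  covariates and the square of the second.  The true coefficients are a
  fixed package convention (`SCENARIO_I_BETA`, intercept 0.7, mild slopes,
  a small negative coefficient on the squared term) chosen once to keep
  counts in the low single digits; the lognormal scale is 0.5.  These
  values are conventions, not published truths.
* **II** (n = 2000 = 20 x 100): `beta = (1.00, -0.10, -0.20, 0.10)` on two
  Bernoulli covariates and their interaction; `theta` the arithmetic
  sequence -0.475, -0.425, …, 0.475; `nu_i = 0.8` for individuals 1–10 and
  1.25 for 11–20.
* **III** (n = 15000 = 100 x 150): `beta = (1, -0.10, 0.05, 0.10, 0.15)`
  on four Bernoulli covariates; `theta` a length-100 sequence from -0.475
  to 0.475; `nu_i` evenly spaced (on the `nu` scale) from 0.8 to 1.25.

The balanced designs are defaults, not requirements.  What these
generators do *not* emulate: covariate measurement error, missingness,
unbalanced cluster sizes, temporal structure, or dispersion-on-covariate
effects — so passing recovery tests here says nothing about robustness to
those features in real data.

## Problem sizes used in checks

The test-suite and reproduction-script runs use desk-scale versions of
the study conditions: chains of 1000–3000 retained draws after 400–800
warmup iterations, 2–10 replicates per design, and `K = 1000` ratio draws
(the diagnostic's nominal reference).  These sizes were chosen as the
package's own verification budget; `m_e` is extremely stable across
replicates (SDs of a few draws out of 1000), so small replicate counts
already pin it down.

## Known limitations

* Overdispersion is capped at the geometric limit (`nu = 0`); data more
  dispersed than geometric cannot be fit well by this family.
* The look-up approach assumes the fitted means stay inside (or near) the
  grid hull; deep extrapolation is flagged but its error is unbounded.
* The dispersion model is log-linear only; covariate-dependent dispersion
  beyond that form is out of scope.
* No gradient-based samplers; random-walk mixing degrades for strongly
  correlated high-dimensional fixed-effect blocks (mitigated by the
  GLM-based proposal covariance).
* The truncation robustness quoted above is a low-count-regime property;
  users with means above ~16 should raise `k` (the build does so
  automatically via `k ~ 2 mu_max`).
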