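# bidisperse

Bayesian **mean-parameterised Conway–Maxwell–Poisson (MPCMP) regression**
for count data that are underdispersed, overdispersed, or — at some
hierarchical level — both at once ("bidispersed"), with a fast
pre-computed look-up table for the rate parameter that makes the model
practical at scale.

## Who this is for

Statisticians and epidemiologists fitting regression models to counts
whose variance does not track the mean: clinical event counts, sports
scores, bids, wickets — anywhere Poisson is wrong in *both* directions
across individuals, so that neither Poisson nor negative binomial
regression is tenable.

## The model

The CMP distribution has pmf

    Pr(Y = y | λ, ν) = λ^y / (y!)^ν / G(λ, ν),     G(λ, ν) = Σ_r λ^r / (r!)^ν,

with rate λ > 0 and dispersion ν ≥ 0: ν = 1 is Poisson, ν < 1
overdispersed (ν = 0 geometric), ν > 1 underdispersed.  The
mean-parameterised family indexes the distribution by its mean μ instead,
which requires solving the mean constraint — equivalently finding the
solitary positive real root of

    Σ_r (r − μ) λ^r / (r!)^ν = 0

— every time the likelihood is evaluated.  Regression enters log-linearly
in both components:

    log μ_i = x₁ᵢᵀβ + offset_i + θ_{g(i)},      log ν_i = x₂ᵢᵀγ,

with optional individual effects θ (sum-to-zero constrained) on the mean
and individual log-dispersions α_i = log ν_i.  Inference is
Metropolis-within-Gibbs: a multivariate-normal random-walk block for β, a
block for θ, and scalar random walks on the log-dispersion scale, with
Robbins–Monro scale adaptation during warmup.

Three interchangeable rate solvers are provided:

* **bisection** — safeguarded Newton on log λ inside a sign-changing
  bracket (vectorised; the exact work-horse);
* **polynomial** — companion-matrix root extraction from the degree-k rate
  polynomial (exact, no iteration);
* **lookup** — bilinear interpolation of a pre-computed grid of log λ over
  (μ, ν) (default: μ from 0.01 to 32 in steps of 0.01, ν from 0 to 10 in
  steps of 0.05), built once in ~20 s and then queried in O(1).  This is
  the method that makes large-n MCMC cheap.

The cost of the approximation is quantified by importance ratios
r = π_exact/π_lookup over K retained draws and the approximate effective
sample size **m_e = (Σr)²/Σr²**: m_e ≈ K means the look-up posterior is
practically indistinguishable from the exact one.

## Worked example

```python
import numpy as np
from bidisperse import (build_table, MCMCConfig, run_mwg, posterior_summary,
                        scenario_II)
from bidisperse.diagnostics import importance_diagnostic

table = build_table()                      # ~20 s, once
data, truth = scenario_II(seed=17, per_individual=50)   # n = 1000, m = 20
chain = run_mwg(data, config=MCMCConfig(iterations=3000, warmup=800,
                                        seed=4, solver="lookup"),
                table=table)
print(posterior_summary(chain).loc[data.x1_names, ["mean", "sd"]].round(3))
diag = importance_diagnostic(chain, data, reference="bisection", K=1000)
print(f"m_e = {diag.m_e:.1f} of {diag.K}")
```

Output:

```
              mean     sd
parameter
intercept    0.979  0.036
x1_bern     -0.087  0.055
x2_bern     -0.218  0.056
x3_int1x2    0.106  0.083
m_e = 1000.0 of 1000
```

The four mean coefficients recover the generating values
(1.00, −0.10, −0.20, 0.10) well within one posterior SD, and the
importance diagnostic shows the look-up approximation costs essentially
none of the 1000 retained draws.

## Command line

```bash
bidisperse build-table --mu-max 32 --mu-step 0.01 --nu-max 10 --nu-step 0.05 --out table.txt
bidisperse simulate --scenario II --seed 1 --out data.csv --truth truth.csv
bidisperse fit --data data.csv --config model.yaml --table table.txt --method lookup --out fit/
bidisperse diagnose --chain fit/chain0 --data data.csv --config model.yaml \
    --table table.txt --reference bisection --out diag/
```

Every output directory receives a `manifest.json` (seeds, config hash,
table hash, version); identical manifests imply byte-identical draws.

## Layout

| module | contents |
| --- | --- |
| `core_dist` | truncated CMP pmf, normalising constant, moments, variates |
| `lambda_solver` | bracketed-Newton and polynomial-root solvers, dispatch |
| `lookup` | grid build, bilinear interpolation/extrapolation, text format |
| `sampler` | data/prior/config containers, Metropolis-within-Gibbs, summaries |
| `diagnostics` | importance ratios, m_e, timing comparisons |
| `synthdata` | the three study designs + a generic scenario generator |
| `dataio`, `cli` | CSV/YAML I/O, chain persistence, manifests, CLI |

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
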