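# ednadensity

Likelihood-based estimation of aquatic-animal density from quantitative
environmental-DNA (eDNA) concentration data.

## The problem

Water samples carry DNA shed by the animals living in them, and modern
quantification (ddPCR copy counts, qPCR concentrations) makes eDNA a
cheap, non-invasive density proxy. The catch is calibration: eDNA
concentration relates to density with enormous replicate-to-replicate
scatter, so a naive regression badly understates uncertainty. This
package implements a one-step likelihood framework for surveys that mix

* **dual-data sites** — eDNA replicates *and* an independent density
  measurement (electrofishing counts, mesocosm stocking, ...), and
* **eDNA-only sites** — eDNA replicates alone.

The dual sites anchor the eDNA–density relationship; the unknown
densities of the eDNA-only sites are estimated **jointly** as latent
parameters, with standard errors and 95% confidence intervals, instead
of being extrapolated post hoc from a fitted regression line.

## The model

For site *i* with replicate eDNA values *w<sub>ik</sub>* (k = 1..K<sub>i</sub>):

> *w<sub>ik</sub>* ~ Distr(μ<sub>i</sub>, θ),  μ<sub>i</sub> = β₀ · D<sub>i</sub>

The mean link is linear through the origin (no animals ⇒ no eDNA).
Three observation families are supported:

| family    | distribution                       | dispersion θ | use when |
|-----------|------------------------------------|--------------|----------|
| `normal`  | Normal(μ, σ²)                      | σ²           | continuous data, mild scatter |
| `poisson` | Poisson(μ)                         | —            | counts, variance ≈ mean |
| `negbin`  | NegBin(μ, r), p = r/(μ+r)          | r            | overdispersed counts (VMR ≫ 1) |

Smaller *r* means stronger overdispersion (Var = μ + μ²/r); r → ∞
recovers the Poisson. Count families need integer data — qPCR ng/L
values are first scaled and rounded (`integerize`).

All parameters (β₀, θ, latent D<sub>i</sub>) are estimated by joint
maximum likelihood on the log scale; uncertainty comes from the inverse
observed information with delta-method SEs, and intervals are log-scale
Wald-t intervals (see `docs/methods.md`). An exhaustive leave-*p*-out
cross-validation harness scores the approach by RMSE, realized 95% CI
coverage, and pairwise rank accuracy, exactly as one would audit a new
monitoring protocol before trusting it.

## Worked example

Simulate an 11-site survey (5 dual sites, 3 replicates each, β₀ = 50
copies/mL per indiv/m², Negative Binomial r = 1) and fit it back:

```bash
ednadensity simulate --seed 11 --out sim
ednadensity fit --edna sim/edna.csv --density sim/density.csv --model negbin --out fit
```

`fit/fit_report.json` contains one record per estimated quantity
(estimate, SE, 95% CI). For this seed:

```
loglik -249.36  converged True
beta0          64.511  SE 15.461   CI [39.379, 105.681]
r               1.162  SE  0.257   CI [ 0.737,   1.832]
D[site001]      7.864  SE  4.616   CI [ 2.348,  26.343]   (truth  7.55)
D[site009]     50.462  SE 29.599   CI [15.077, 168.893]   (truth 44.85)
```

The slope β₀ and dispersion r are recovered within their intervals, and
each eDNA-only site gets a density estimate whose interval covers the
simulated truth (`sim/truth.csv`). The wide intervals are honest: with
three heavily overdispersed replicates per site, that *is* the
information content of the data.

Cross-validation and diagnostics work the same way:

```bash
ednadensity cv --edna edna.csv --density density.csv --model negbin --dual-sites 5 --out cv
ednadensity diagnose --edna edna.csv --density density.csv
```

`cv` writes per-split held-out records plus a summary JSON (`rmse`,
`coverage`, `rank_accuracy`, `n_splits`, `n_failed`); `diagnose` prints
the per-site variance-to-mean ratios and the replicate-level
eDNA–density correlation.

Everything is also available as a library:

```python
from ednadensity import SimulationConfig, simulate_dataset, fit, ModelSpec

dataset, truth = simulate_dataset(SimulationConfig(seed=11))
result = fit(dataset, ModelSpec("negbin"))
print(result.estimates.beta0, result.ci95["beta0"])
```

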