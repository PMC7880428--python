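# geoadditive

Bayesian geo-additive logistic regression for small-area prevalence mapping
from pooled household surveys.

## The problem

Health-indicator prevalence (the motivating application is female genital
mutilation/cutting, FGM/C, among 0–14-year-old girls across a country's
states) is estimated from pooled cross-sectional surveys (DHS and MICS
rounds).  Such data are clustered — girls nest within mothers, mothers
within states — and spatially and temporally autocorrelated, so ordinary
logistic regression understates uncertainty and cannot localise risk.
This package fits structured additive regression (STAR) models for a
binary outcome `y ~ Bernoulli(p)`:

```
logit(p_i) = z_i'ω + f(age_i) + f(year_i) + f_str(s_i) + f_unstr(s_i) + ξ(s_i, t_i)
```

* `z_i'ω` — dummy-coded fixed effects (education, residence, mother's cut
  status, support for the practice, survey family) under flat priors;
* `f(age)`, `f(year)` — Bayesian P-splines: cubic B-spline / ordered-step
  bases with second-order random-walk (RW2) priors;
* `f_str(s)` — spatially structured state effect with an intrinsic Markov
  random field (ICAR) prior on the contiguity graph:
  `f_str(s) | rest ~ N(mean of neighbours, τ²_str / N_s)`;
* `f_unstr(s)` — iid Gaussian unstructured heterogeneity;
* `ξ` — optional space–time interaction, iid or temporally smooth per state.

Inference is MCMC: Metropolis–Hastings block updates with iteratively
weighted least squares (IWLS) proposals for all coefficient blocks, and
conjugate inverse-gamma Gibbs updates `IG(a + rank(K)/2, b + β'Kβ/2)` for
every smoothing variance (defaults a = 1, b = 0.0005).  Model choice across
a nested suite m1–m6 uses the deviance information criterion
DIC = D̄ + p_D; spatial clustering is tested with global Moran's I
(analytic normal approximation and permutation Monte Carlo).

Because the original survey microdata are access-restricted, the package
ships a first-class synthetic generator that emulates the pooled
multi-survey structure (six rounds 2003–2016, girls nested in mothers,
covariates shared within a mother, spatial + smooth + fixed effects), so
every stage is testable end to end.

## Worked example

```python
from geoadditive import (MCMCConfig, build_model_terms, dic, draw_truth,
                         make_lattice_graph, posterior_odds_ratios,
                         run_mcmc, simulate_dataset)

graph = make_lattice_graph(6, 6)                  # 36 regions, national scale
truth = draw_truth(graph, seed=1)
data = simulate_dataset(truth, graph, n_mothers=3000, seed=2)

terms = build_model_terms(data, graph, model="m6", n_interior_knots=8)
samples = run_mcmc(data["fgm"].to_numpy(float),
                   terms, MCMCConfig(n_iter=2000, burn_in=500, thin=5, seed=3))
print(posterior_odds_ratios(samples, "mother_cut"))
```

Output (from `python examples/02_fit_geoadditive_model.py`):

```
DIC 4436.4 = mean deviance 4397.6 + effective parameters 38.8
 covariate    level       por  por_at_mean     lower    upper
mother_cut No (ref)  1.000000     1.000000       NaN      NaN
mother_cut      Yes 17.306788    17.246014 14.745378 20.85384
(the generator's true odds ratio is 18)
spatial risk classes: {'nonsignificant': 28, 'low': 4, 'high': 4}
correlation of posterior-mean structured field with truth: 0.80
```

A posterior odds ratio (POR) of 17.3 means a girl whose mother was cut has
about 17 times the odds of being cut herself, credible interval [14.7,
20.9]; the generating truth was 18.  Regions classified `high`/`low` have
95% credible intervals for the total spatial effect entirely above/below
zero.  The `examples/` directory has one short script per capability:
simulation, fitting, the DIC model suite, Moran's I, weighted crosstabs.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
runs the whole pipeline from scratch — generates a pooled synthetic
dataset, fits the full space–time interaction model, and prints the DIC,
a posterior odds ratio, per-state prevalence and a Moran's I test — then
writes the results JSON.

## Layout

```
src/geoadditive/   graph, moran, penalties, basis, terms, model,
                   simulate, sampler, inference, pipeline
examples/          narrative scripts, one per capability
tests/             unit + property tests and the acceptance suite
docs/methods.md    the statistical methods note
```
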