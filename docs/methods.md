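# Methods

## Model

For girl *i* with binary cut status `y_i`, state `s_i ∈ {1..S}` and survey
round `t_i`, the package fits the structured additive logit model

```
logit(p_i) = z_i'ω + f_age(age_i) + f_year(t_i) + f_str(s_i) + f_unstr(s_i) + ξ(s_i, t_i)
```

with `y_i ~ Bernoulli(p_i)` conditionally independent given the predictor.
Each non-fixed component `f_j = X_j β_j` carries a Gaussian smoothing prior
`π(β_j | τ_j²) ∝ (τ_j²)^(−rank(K_j)/2) exp(−β_j'K_j β_j / 2τ_j²)` with a
structure-specific penalty `K_j`:

| component | design | penalty K | rank |
|---|---|---|---|
| fixed effects ω | dummy coding, stated reference level | none (flat prior) | — |
| f_age | cubic B-splines, equidistant knots (default 20 interior) | RW2 (squared second differences) | M−2 |
| f_year | ordered-step basis over the observed survey years | RW2, equal-weight differences | T−2 |
| f_str | state indicators | intrinsic MRF: diag(N_s) − adjacency | S−c |
| f_unstr | state indicators | identity (iid) | S |
| ξ iid | state×year cell indicators | identity | S·T |
| ξ smooth | state×year cell indicators | block-diagonal RW2 over years per state | S(T−2) |

The MRF prior makes each state effect conditionally normal around the mean
of its contiguous neighbours with variance `τ²_str / N_s`; it is improper
(rank S−1 on a connected graph), so all penalised components are kept
**centred on zero** with the removed mean absorbed into the intercept.
Centring is exact for every design here because all non-fixed design rows
sum to one (indicators and B-spline partition of unity).

Assumptions: the spatial decomposition into structured + unstructured parts
is identified only through the priors and the centring convention;
survey-year spacing is ignored in the RW2 year penalty (years are treated
as ordered categories); the survey-family fixed effect is collinear with a
function of the year effect when each round is a single survey family, and
is identified only weakly through the RW2 penalty — this mirrors the pooled
DHS/MICS application and is intentional.

## Sampler

All coefficient blocks are updated by Metropolis–Hastings with an IWLS
proposal (Gamerman-type): at the current state,
`P = X'WX + K/τ²`, `m = P⁻¹X'W(ỹ − η_rest)` with `W = diag(p(1−p))` floored
at 1e−6 and working response `ỹ = η + (y−p)/W`; the proposal is
`N(m, P⁻¹)`, the reverse-move density is rebuilt at the proposed state, and
the exact Bernoulli likelihood enters the acceptance ratio.  Fixed effects
form one jointly-updated block (flat prior).  Smoothing variances are
Gibbs-updated from the conjugate `IG(a + rank(K)/2, b + β'Kβ/2)` full
conditional; defaults `a = 1`, `b = 0.0005` (diffuse).

Update order is deterministic — fixed, smooths, spatial, interaction, then
variances — and a single chain is run by default.  The default schedule is
20,000 iterations, 4,000 burn-in (16,000 kept), thinned by 20 (800 stored).
The whole chain is reproducible bitwise from `MCMCConfig.seed`.

Numerical choices: Cholesky factorisation of the proposal precision with
escalating jitter (from 1e−10 × mean diagonal) if singular; stable
log-likelihood via `logaddexp`; re-centring applied after every accepted
penalised-block update.  Re-centring technically perturbs detailed balance
for the identity-penalty blocks (the iid prior is not shift-invariant);
this is the standard practice for structured/unstructured spatial pairs,
whose sum alone is likelihood-identified, and the validation suite shows
correct fixed-effect coverage and posterior moments under it.

## Model suite and assessment

The nested suite m1–m6 (spatial-only → + survey → + covariates and age
smooth → + space–time interaction as smooth or iid) plus single-survey
variants m1*/m3* without the year term.  Models are compared by
`DIC = D̄ + p_D`, `p_D = D̄ − D(η̄)`, computed on the girl-level Bernoulli
deviance (saturated log-likelihood zero); a grouped binomial deviance with
the `0·log 0 = 0` convention is provided for per-region deviance maps, and
its contributions sum exactly to the total.  Negative `p_D` is reported
with a warning, never hidden.  The best model is the DIC minimum with ties
broken toward the model listed earlier (simpler).  Posterior odds ratios
are reported both as the posterior mean of `exp(β)` and as
`exp(posterior mean β)`, with equal-tailed 95% intervals; per-state
prevalence averages `logit⁻¹(η_i)` within state per draw; spatial effects
are classified high/low/nonsignificant by whether the 95% credible interval
of the total (default) or structured-only effect excludes zero.  No
multiplicity adjustment is applied across regions (raw per-state
intervals) — a documented caveat.

Moran's I uses binary contiguity weights; the analytic test uses the
normality-assumption null mean `−1/(S−1)` and variance; the permutation
test uses the `(1+k)/(1+n)` estimator, so p is never exactly zero.

## Synthetic generator: what it emulates, and what not

The generator states a fixed world resembling the pooled application:

* six survey rounds (2003, 2007, 2008, 2011, 2013, 2016), alternating
  DHS/MICS, with round shares proportional to the six published per-round
  sample sizes;
* girls nested in mothers (1 + Poisson(0.7) daughters, mean 1.7 — the
  published girls-to-mothers ratio), all mother-level covariates shared
  between sisters;
* intercept −3.0 and a mother's-cut-status log-odds of log 18, yielding
  ~0.2 marginal prevalence (the national scale); education/residence/
  support effects of 0.2–0.8 on the logit scale;
* τ²_str = 0.5 (structured spatial sd ≈ 0.7 — dominant, as in disease
  mapping practice), τ²_unstr = 0.05, τ²_ξ = 0.1; age and year smooths are
  RW2-subspace draws standardised to sd 0.3 and 0.25;
* Gamma(4, ¼) survey weights normalised to mean one, used only by the
  descriptive crosstabs, never the Bayesian fit;
* missingness, when injected, is MCAR on covariate cells only.

It does **not** emulate two-stage cluster sampling (strata/PSUs), real
covariate distributions, mother-level random effects beyond shared
covariates, or informative missingness.  A green recovery test therefore
establishes that the sampler recovers the stated generative structure, not
that the model is robust to design effects absent from that structure.

## Validation scaling

The validation suite runs on one CPU: the posterior-oracle check uses a
dense-grid numerical posterior on 200 observations; parameter recovery
uses one 6×6-lattice fit (~10,000 girls, 4,000 iterations); coverage uses
50 light replicates (~1,200 girls, 900 iterations each); the DIC selection
study uses 10 replicates of ~4,000 girls with 1,600-iteration chains and
an interaction variance of 0.5 so the signal is identifiable at that
sample size.  Shorter chains widen Monte-Carlo error but none of the
assertions were loosened to compensate.

## Known limitations

* Single-chain default; no formal convergence diagnostics beyond
  acceptance rates (multi-seed agreement is exercised in tests).
* The intrinsic MRF sampler requires a connected graph; disconnected maps
  must be handled per component by the caller.
* DIC is the only model-comparison criterion (no WAIC/LOO).
* No survey-weighted likelihood: weights enter descriptive tables only.
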