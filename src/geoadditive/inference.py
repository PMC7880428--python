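"""Posterior summaries and model assessment.

Deviance and DIC for model comparison across the nested suite, posterior
odds-ratio tables for the fixed effects, per-region posterior prevalence
p_k = E[logit^{-1}(eta) | region k], and the three-way significance
classification of spatial effects (high / low / nonsignificant by whether
the 95% credible interval of the region effect excludes zero).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .graph import AdjacencyGraph
from .model import build_model_terms
from .sampler import MCMCConfig, PosteriorSamples, run_mcmc

__all__ = [
    "bernoulli_deviance",
    "deviance_at",
    "dic",
    "posterior_odds_ratios",
    "predicted_prevalence",
    "classify_spatial_effects",
    "fit_model_suite",
    "weighted_prevalence_table",
    "prevalence_decline",
]


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """x * log(y) with the saturated-deviance convention 0 * log 0 = 0."""
    out = np.zeros_like(np.asarray(x, dtype=float))
    nz = np.asarray(x) != 0
    out[nz] = np.asarray(x)[nz] * np.log(np.asarray(y, dtype=float)[nz])
    return out


def bernoulli_deviance(y, n, mu_hat) -> tuple[float, np.ndarray]:
    """Grouped binomial deviance against the saturated model.

    Per unit k with y_k successes out of n_k trials and fitted probability
    mu_k:  d_k = 2 [ y log(y / (n mu)) + (n - y) log((n - y) / (n (1 - mu))) ].
    Returns (total, per-unit contributions); contributions sum to the total.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu_hat, dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= y <= n per unit")
    bad = ((mu <= 0) & (y > 0)) | ((mu >= 1) & (y < n))
    if np.any(bad):
        raise ValueError("fitted probability 0 or 1 contradicts the observed counts "
                         "(infinite deviance)")
    mu = np.clip(mu, 1e-300, 1 - 1e-16)
    d = 2.0 * (_xlogy(y, y / (n * mu)) + _xlogy(n - y, (n - y) / (n * (1.0 - mu))))
    d = np.maximum(d, 0.0)  # guard roundoff at the saturated point
    return float(d.sum()), d


def deviance_at(y: np.ndarray, eta: np.ndarray) -> float:
    """Girl-level Bernoulli deviance -2 log L(eta) (saturated log-lik = 0)."""
    y = np.asarray(y, dtype=float)
    return float(2.0 * (np.sum(np.logaddexp(0.0, eta)) - np.sum(y * eta)))


def dic(samples: PosteriorSamples, y) -> tuple[float, float, float, float]:
    """Deviance information criterion from the retained draws.

    Returns (dic, p_d, d_bar, d_at_mean) with d_bar the posterior mean
    deviance, d_at_mean the deviance at the posterior-mean linear predictor,
    p_d = d_bar - d_at_mean and dic = d_bar + p_d.  A negative p_d is
    reported with a warning, never hidden.
    """
    if samples.n_draws < 2:
        raise ValueError("need at least 2 retained draws for the DIC")
    y = np.asarray(y, dtype=float)
    etas = samples.linear_predictors()
    devs = 2.0 * (np.logaddexp(0.0, etas).sum(axis=1) - etas @ y)
    d_bar = float(devs.mean())
    d_at_mean = deviance_at(y, etas.mean(axis=0))
    p_d = d_bar - d_at_mean
    if p_d < -1e-8:  # roundoff-negative values are not worth a warning
        import warnings

        warnings.warn(f"negative effective number of parameters p_d = {p_d:.3f}")
    return d_bar + p_d, p_d, d_bar, d_at_mean


def posterior_odds_ratios(
    samples: PosteriorSamples, covariate: str, level: float = 0.95
) -> pd.DataFrame:
    """Posterior odds-ratio table for one dummy-coded fixed covariate.

    One row per level; the reference row carries POR 1.00 with an empty
    interval.  Both the posterior mean of exp(beta) (`por`) and
    exp(posterior mean beta) (`por_at_mean`) are reported.
    """
    fixed = samples.term("fixed")
    if covariate not in fixed.components:
        raise ValueError(
            f"{covariate!r} is not a fixed-effect covariate of this fit; smooth and "
            f"spatial terms are reported as curves/maps, not odds ratios"
        )
    span, levels, ref = fixed.components[covariate]
    draws = samples.coef["fixed"][:, span]
    alpha = (1.0 - level) / 2.0
    rows = []
    j = 0
    for lev in levels:
        if lev == ref:
            rows.append({"covariate": covariate, "level": f"{lev} (ref)", "por": 1.0,
                         "por_at_mean": 1.0, "lower": np.nan, "upper": np.nan})
            continue
        ors = np.exp(draws[:, j])
        rows.append(
            {
                "covariate": covariate,
                "level": lev,
                "por": float(ors.mean()),
                "por_at_mean": float(np.exp(draws[:, j].mean())),
                "lower": float(np.quantile(ors, alpha)),
                "upper": float(np.quantile(ors, 1.0 - alpha)),
            }
        )
        j += 1
    return pd.DataFrame(rows)


def predicted_prevalence(
    samples: PosteriorSamples, states, n_regions: int, level: float = 0.95
) -> pd.DataFrame:
    """Per-region posterior prevalence with credible bands.

    For each retained draw, each girl's eta is inverse-logit transformed and
    averaged within her region; the draws of these region means are then
    summarised.  Regions without observations are returned with NaN and
    flagged ``borrowed`` (their risk is carried by the spatial effect alone).
    """
    states0 = np.asarray(states, dtype=int) - 1
    if states0.min() < 0 or states0.max() >= n_regions:
        raise ValueError("state index out of range")
    probs = expit(samples.linear_predictors())
    counts = np.bincount(states0, minlength=n_regions)
    sums = np.vstack(
        [np.bincount(states0, weights=row, minlength=n_regions) for row in probs]
    )
    alpha = (1.0 - level) / 2.0
    mean = np.full(n_regions, np.nan)
    lo = np.full(n_regions, np.nan)
    hi = np.full(n_regions, np.nan)
    occupied = counts > 0
    per_draw = sums[:, occupied] / counts[occupied]
    mean[occupied] = per_draw.mean(axis=0)
    lo[occupied] = np.quantile(per_draw, alpha, axis=0)
    hi[occupied] = np.quantile(per_draw, 1.0 - alpha, axis=0)
    return pd.DataFrame(
        {
            "state": np.arange(1, n_regions + 1),
            "n_girls": counts,
            "prevalence": mean,
            "lower": lo,
            "upper": hi,
            "borrowed": ~occupied,
        }
    )


def classify_spatial_effects(
    samples: PosteriorSamples, level: float = 0.95, which: str = "total"
) -> pd.DataFrame:
    """Classify each region's spatial effect as high / low / nonsignificant.

    ``high`` if the lower credible bound of the effect is above zero,
    ``low`` if the upper bound is below zero, else ``nonsignificant`` —
    the black/white/grey map convention.  ``which`` selects the total
    spatial effect f_str + f_unstr (default) or ``structured`` alone.
    """
    if which == "total":
        draws = samples.coef["f_str"] + samples.coef["f_unstr"]
    elif which == "structured":
        draws = samples.coef["f_str"]
    else:
        raise ValueError("which must be 'total' or 'structured'")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1.0 - alpha, axis=0)
    cls = np.where(lo > 0, "high", np.where(hi < 0, "low", "nonsignificant"))
    labels = samples.term("f_str").column_labels
    return pd.DataFrame(
        {"state": np.arange(1, draws.shape[1] + 1), "label": labels,
         "effect": draws.mean(axis=0), "lower": lo, "upper": hi, "class": cls}
    )


def fit_model_suite(
    data: pd.DataFrame,
    graph: AdjacencyGraph,
    models=("m1", "m2", "m3", "m4", "m5", "m6"),
    config: MCMCConfig | None = None,
    **build_kwargs,
) -> tuple[pd.DataFrame, dict[str, PosteriorSamples]]:
    """Fit the requested nested models under a shared seed and tabulate DIC.

    Returns the DIC table (with the lowest-DIC model flagged ``best``; ties
    break toward the simpler model, i.e. earlier in the requested order) and
    the fitted samples per model.
    """
    models = list(models)
    if len(set(models)) != len(models):
        raise ValueError("duplicate model ids in the suite request")
    cfg = config or MCMCConfig()
    y = np.asarray(data["fgm"], dtype=float)
    rows, fits = [], {}
    for mid in models:
        terms = build_model_terms(data, graph, model=mid, **build_kwargs)
        samples = run_mcmc(y, terms, cfg)
        d, p_d, d_bar, d_hat = dic(samples, y)
        fits[mid] = samples
        rows.append({"model": mid, "dic": d, "p_d": p_d, "d_bar": d_bar,
                     "d_at_mean": d_hat})
    table = pd.DataFrame(rows)
    if len(table):
        best = table["dic"].round(10).idxmin()  # idxmin takes the first minimum
        table["best"] = False
        table.loc[best, "best"] = True
    return table, fits


def weighted_prevalence_table(
    table: pd.DataFrame, weights, by: str, outcome: str = "fgm"
) -> pd.DataFrame:
    """Survey-weighted prevalence crosstab for one covariate.

    Per level of ``by``: the weighted number of girls and the weighted
    percent cut.  With all weights equal this reproduces the unweighted
    proportions exactly.
    """
    if by not in table.columns:
        raise ValueError(f"unknown covariate {by!r}; columns: {list(table.columns)}")
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != len(table) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per row")
    y = np.asarray(table[outcome], dtype=float)
    rows = []
    for lev, idx in table.groupby(by, observed=True).indices.items():
        ww = w[idx]
        rows.append(
            {
                by: lev,
                "weighted_n": float(ww.sum()),
                "weighted_percent_cut": float(100.0 * (ww * y[idx]).sum() / ww.sum()),
            }
        )
    return pd.DataFrame(rows).sort_values(by).reset_index(drop=True)


def prevalence_decline(earlier_percent: float, later_percent: float) -> float:
    """Percentage-point change between two printed prevalence figures."""
    return float(earlier_percent - later_percent)
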