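"""Synthetic pooled-survey generator for girl-level cut-status data.

Emulates the structure of six pooled national household surveys
(three DHS + three MICS rounds, 2003-2016): girls nest within mothers,
mothers live in one of S contiguous regions, and each girl's probability of
having been cut follows the full geo-additive logit model

    logit p_i = beta0 + z_i' omega + f(age_i) + f(year_i)
                + f_str(s_i) + f_unstr(s_i) + xi(s_i, year_i)

with f_str an intrinsic-MRF draw, f_unstr iid Gaussian, the smooths RW2
paths, and xi either iid or temporally smooth per region.  Girls of the same
mother share all mother-level covariates, which induces the within-mother
dependence of real survey data; conditional on covariates the outcomes are
independent Bernoulli draws.

Defaults state a plausible world at the national scale of the application:
marginal prevalence around 0.2, a strong mother's-cut-status effect
(odds ratio 18), moderate structured spatial variation and a weaker
unstructured remainder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .graph import AdjacencyGraph, sample_igmrf
from .penalties import rw2_penalty

__all__ = [
    "GeneratorConfig",
    "TruthParams",
    "make_lattice_graph",
    "draw_truth",
    "simulate_dataset",
    "inject_missingness",
    "listwise_deletion",
    "write_truth",
    "read_truth",
]

YEARS = (2003, 2007, 2008, 2011, 2013, 2016)
#: survey family per round (three DHS, three MICS) and pooled sample shares
#: proportional to the six printed per-round sample sizes.
SURVEY_OF_YEAR = {2003: "DHS", 2007: "MICS", 2008: "DHS", 2011: "MICS", 2013: "DHS", 2016: "MICS"}
_ROUND_SIZES = (3281, 7768, 17691, 16874, 25176, 17529)
YEAR_SHARES = {y: n / sum(_ROUND_SIZES) for y, n in zip(YEARS, _ROUND_SIZES)}

AGE_GRID = np.arange(15, 50)  # mother's age support

DEFAULT_FIXED_EFFECTS: dict[str, dict[str, float]] = {
    "education": {"None": 0.6, "Primary": 0.4, "Secondary": 0.2, "Higher": 0.0},
    "residence": {"Rural": 0.3, "Urban": 0.0},
    "mother_cut": {"Yes": float(np.log(18.0)), "No": 0.0},
    "support": {"Yes": 0.8, "No": 0.0},
    "survey": {"MICS": 0.1, "DHS": 0.0},
}

#: marginal covariate distributions for mothers (levels -> probability)
COVARIATE_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "education": {"None": 0.35, "Primary": 0.20, "Secondary": 0.30, "Higher": 0.15},
    "residence": {"Rural": 0.60, "Urban": 0.40},
    "mother_cut": {"Yes": 0.35, "No": 0.65},
    "support": {"Yes": 0.25, "No": 0.75},
    "wealth": {"Lowest": 0.22, "Second": 0.21, "Middle": 0.20, "Fourth": 0.19, "Highest": 0.18},
}


@dataclass
class GeneratorConfig:
    """Stated-world parameters of the generator."""

    intercept: float = -3.0
    fixed_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FIXED_EFFECTS.items()}
    )
    tau2_str: float = 0.5
    tau2_unstr: float = 0.05
    tau2_xi: float = 0.1
    sd_age: float = 0.3  # amplitude of the mother's-age smooth
    sd_year: float = 0.25  # amplitude of the year effect
    interaction: str = "iid"  # 'iid' | 'smooth' | 'none'
    years: tuple[int, ...] = YEARS

    def validate(self) -> None:
        for nm, v in (("tau2_str", self.tau2_str), ("tau2_unstr", self.tau2_unstr),
                      ("tau2_xi", self.tau2_xi)):
            if v < 0:
                raise ValueError(f"{nm} must be >= 0 (0 switches the component off)")
        if self.sd_age < 0 or self.sd_year < 0:
            raise ValueError("smooth amplitudes must be >= 0")
        if self.interaction not in ("iid", "smooth", "none"):
            raise ValueError("interaction must be 'iid', 'smooth' or 'none'")


@dataclass
class TruthParams:
    """The generating parameters: every right-hand-side piece of the logit model."""

    intercept: float
    fixed_effects: dict[str, dict[str, float]]
    f_age: np.ndarray  # tabulated on AGE_GRID, mean zero
    f_year: dict[int, float]  # mean zero over years
    f_str: np.ndarray  # per region, sum zero
    f_unstr: np.ndarray  # per region, mean zero
    xi: np.ndarray  # (S, T) interaction, mean zero
    tau2_str: float
    tau2_unstr: float
    tau2_xi: float
    years: tuple[int, ...]

    def f_age_at(self, ages) -> np.ndarray:
        return np.interp(np.asarray(ages, dtype=float), AGE_GRID, self.f_age)


def make_lattice_graph(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-contiguity lattice — a stand-in for a national contiguity map.

    A 6x6 lattice has 36 regions, matching the scale of Nigeria's 36 states
    + FCT application the model is designed for.
    """
    if rows * cols < 2:
        raise ValueError("need at least two regions")
    labels = tuple(f"r{i}c{j}" for i in range(rows) for j in range(cols))
    edges = set()
    for i in range(rows):
        for j in range(cols):
            k = i * cols + j
            if j + 1 < cols:
                edges.add((k, k + 1))
            if i + 1 < rows:
                edges.add((k, k + cols))
    return AdjacencyGraph(labels=labels, edges=frozenset(edges))


def _rw2_path(m: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """A smooth mean-zero path: a draw from the RW2 prior's penalised subspace,
    standardised to the stated amplitude ``sd``."""
    if sd == 0:
        return np.zeros(m)
    k = rw2_penalty(m).matrix
    eigval, eigvec = np.linalg.eigh(k)
    keep = eigval > 1e-9 * eigval.max()
    z = rng.standard_normal(int(keep.sum()))
    path = eigvec[:, keep] @ (z / np.sqrt(eigval[keep]))
    path -= path.mean()
    s = path.std()
    return path * (sd / s) if s > 0 else path


def draw_truth(
    graph: AdjacencyGraph,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TruthParams:
    """Draw one set of true parameters from the generative priors."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    s = graph.n_regions
    t = len(cfg.years)

    if cfg.tau2_str > 0:
        f_str = sample_igmrf(graph, cfg.tau2_str, 1, rng=rng)[0]
    else:
        f_str = np.zeros(s)
    if cfg.tau2_unstr > 0:
        f_unstr = rng.normal(0.0, np.sqrt(cfg.tau2_unstr), s)
        f_unstr -= f_unstr.mean()
    else:
        f_unstr = np.zeros(s)

    f_age = _rw2_path(len(AGE_GRID), cfg.sd_age, rng)
    f_year = _rw2_path(t, cfg.sd_year, rng)

    if cfg.interaction == "none" or cfg.tau2_xi == 0:
        xi = np.zeros((s, t))
    elif cfg.interaction == "iid":
        xi = rng.normal(0.0, np.sqrt(cfg.tau2_xi), (s, t))
        xi -= xi.mean()
    else:  # per-region smooth trajectories
        xi = np.vstack([_rw2_path(t, np.sqrt(cfg.tau2_xi), rng) for _ in range(s)])
        xi -= xi.mean()

    return TruthParams(
        intercept=cfg.intercept,
        fixed_effects={k: dict(v) for k, v in cfg.fixed_effects.items()},
        f_age=f_age,
        f_year=dict(zip(cfg.years, f_year)),
        f_str=f_str,
        f_unstr=f_unstr,
        xi=xi,
        tau2_str=cfg.tau2_str,
        tau2_unstr=cfg.tau2_unstr,
        tau2_xi=cfg.tau2_xi,
        years=tuple(cfg.years),
    )


def _sample_levels(dist: dict[str, float], n: int, rng: np.random.Generator) -> np.ndarray:
    levels = list(dist)
    p = np.array([dist[l] for l in levels], dtype=float)
    return np.array(levels)[rng.choice(len(levels), size=n, p=p / p.sum())]


def simulate_dataset(
    truth: TruthParams,
    graph: AdjacencyGraph,
    n_mothers: int = 10000,
    girls_per_mother_mean: float = 1.7,
    survey_design: dict[int, tuple[str, float]] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Forward-simulate a pooled girl-level table under ``truth``.

    Mothers are assigned a region (uniform), a survey round (by the stated
    shares) and mother-level covariates; each mother has 1 + Poisson(mean-1)
    daughters who inherit her covariates.  Girl outcomes are Bernoulli with
    the model's inverse-logit probability.
    """
    if n_mothers < 1:
        raise ValueError("empty design: need at least one mother")
    if rng is None:
        rng = np.random.default_rng(seed)
    if survey_design is None:
        survey_design = {y: (SURVEY_OF_YEAR[y], YEAR_SHARES[y]) for y in truth.years}
    years = sorted(survey_design)
    shares = np.array([survey_design[y][1] for y in years], dtype=float)
    if not np.isclose(shares.sum(), 1.0, atol=1e-6):
        raise ValueError("survey-year shares must sum to 1")
    year_index = {y: k for k, y in enumerate(truth.years)}
    for y in years:
        if y not in year_index:
            raise ValueError(f"survey year {y} not present in the truth's year support")

    s = graph.n_regions
    m_state = rng.integers(0, s, size=n_mothers)
    m_year = np.array(years)[rng.choice(len(years), size=n_mothers, p=shares / shares.sum())]
    m_survey = np.array([survey_design[y][0] for y in m_year])
    m_age = np.clip(np.round(rng.normal(30.0, 8.0, n_mothers)), 15, 49)
    m_cov = {
        name: _sample_levels(dist, n_mothers, rng)
        for name, dist in COVARIATE_DISTRIBUTIONS.items()
    }
    lam = max(girls_per_mother_mean - 1.0, 0.0)
    m_girls = 1 + rng.poisson(lam, n_mothers)
    m_weight = rng.gamma(4.0, 0.25, n_mothers)
    m_weight /= m_weight.mean()

    idx = np.repeat(np.arange(n_mothers), m_girls)
    state0 = m_state[idx]
    year = m_year[idx]
    eta = (
        truth.intercept
        + truth.f_age_at(m_age[idx])
        + np.array([truth.f_year[y] for y in truth.years])[
            np.vectorize(year_index.get)(year)
        ]
        + truth.f_str[state0]
        + truth.f_unstr[state0]
        + truth.xi[state0, np.vectorize(year_index.get)(year)]
    )
    for name, coefs in truth.fixed_effects.items():
        if name == "survey":
            vals = m_survey[idx]
        elif name in m_cov:
            vals = m_cov[name][idx]
        else:
            continue
        eta = eta + np.array([coefs.get(v, 0.0) for v in vals])

    y_girl = rng.binomial(1, expit(eta))
    table = pd.DataFrame(
        {
            "fgm": y_girl,
            "state": state0 + 1,  # 1-based region index, label in state_label
            "state_label": np.array(graph.labels)[state0],
            "year": year,
            "survey": m_survey[idx],
            "mother_id": idx,
            "mother_age": m_age[idx],
            "weight": m_weight[idx],
        }
    )
    for name in COVARIATE_DISTRIBUTIONS:
        table[name] = m_cov[name][idx]
    return table


#: covariate columns eligible for injected missingness (never the outcome)
MISSABLE_COLUMNS = ("mother_age", "education", "residence", "mother_cut", "support", "wealth")


def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    seed: int | None = None,
    columns: tuple[str, ...] = MISSABLE_COLUMNS,
) -> pd.DataFrame:
    """Blank covariate cells completely at random; the outcome is never blanked."""
    if not 0 <= rate < 1:
        raise ValueError("missingness rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    for col in columns:
        if col not in out.columns:
            continue
        mask = rng.random(len(out)) < rate
        if out[col].dtype.kind in "iu":
            out[col] = out[col].astype(float)
        out.loc[mask, col] = np.nan
    return out


def listwise_deletion(
    table: pd.DataFrame, columns: tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, int]:
    """Drop every row with at least one missing analysis cell.

    Returns the complete-case table and the number of rows removed.
    """
    cols = [c for c in (columns or table.columns) if c in table.columns]
    keep = table[cols].notna().all(axis=1)
    return table.loc[keep].reset_index(drop=True), int((~keep).sum())


def write_truth(truth: TruthParams, path: str | Path) -> None:
    payload = {
        "intercept": truth.intercept,
        "fixed_effects": truth.fixed_effects,
        "f_age": truth.f_age.tolist(),
        "f_year": {str(k): v for k, v in truth.f_year.items()},
        "f_str": truth.f_str.tolist(),
        "f_unstr": truth.f_unstr.tolist(),
        "xi": truth.xi.tolist(),
        "tau2_str": truth.tau2_str,
        "tau2_unstr": truth.tau2_unstr,
        "tau2_xi": truth.tau2_xi,
        "years": list(truth.years),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> TruthParams:
    d = json.loads(Path(path).read_text())
    return TruthParams(
        intercept=d["intercept"],
        fixed_effects=d["fixed_effects"],
        f_age=np.asarray(d["f_age"]),
        f_year={int(k): v for k, v in d["f_year"].items()},
        f_str=np.asarray(d["f_str"]),
        f_unstr=np.asarray(d["f_unstr"]),
        xi=np.asarray(d["xi"]),
        tau2_str=d["tau2_str"],
        tau2_unstr=d["tau2_unstr"],
        tau2_xi=d["tau2_xi"],
        years=tuple(d["years"]),
    )
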