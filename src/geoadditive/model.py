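"""Model-suite construction: from a girl-level table to a list of ModelTerms.

The nested suite fitted to the pooled data, all sharing the spatial
decomposition f_str (intrinsic MRF) + f_unstr (iid region effect):

=====  ==============================================================
m1     spatial + f(year)
m2     m1 + survey fixed effect
m3     m1 + categorical covariates + f(mother's age)
m4     m3 + survey
m5     m4 + space-time interaction as a smooth (RW2 over years per region)
m6     m4 + space-time interaction as an iid random effect
m1* / m3*   single-survey variants of m1 / m3 without the year smooth
=====  ==============================================================

Year enters as an RW2-penalised step function over the observed survey
years (equal-weight second differences; the years are treated as ordered
categories).  Mother's age enters as a cubic P-spline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .basis import bspline_basis
from .graph import AdjacencyGraph, mrf_precision
from .penalties import block_diag_penalty, identity_penalty, rw2_penalty
from .terms import ModelTerm, combine_fixed_terms, encode_categorical

__all__ = ["MODEL_IDS", "DEFAULT_COVARIATES", "DEFAULT_REFERENCES", "build_model_terms"]

MODEL_IDS = ("m1", "m2", "m3", "m4", "m5", "m6", "m1*", "m3*")

DEFAULT_COVARIATES = ("education", "residence", "mother_cut", "support")

DEFAULT_REFERENCES = {
    "education": "Higher",
    "residence": "Urban",
    "mother_cut": "No",
    "support": "No",
    "wealth": "Highest",
    "survey": "DHS",
}

_FEATURES = {
    "m1": dict(year=True, survey=False, covars=False, age=False, interaction=None),
    "m2": dict(year=True, survey=True, covars=False, age=False, interaction=None),
    "m3": dict(year=True, survey=False, covars=True, age=True, interaction=None),
    "m4": dict(year=True, survey=True, covars=True, age=True, interaction=None),
    "m5": dict(year=True, survey=True, covars=True, age=True, interaction="smooth"),
    "m6": dict(year=True, survey=True, covars=True, age=True, interaction="iid"),
    "m1*": dict(year=False, survey=False, covars=False, age=False, interaction=None),
    "m3*": dict(year=False, survey=False, covars=True, age=True, interaction=None),
}


def _state_groups(data: pd.DataFrame, graph: AdjacencyGraph) -> np.ndarray:
    s = np.asarray(data["state"], dtype=int)
    if s.min() < 1 or s.max() > graph.n_regions:
        raise ValueError(
            f"state indices must lie in 1..{graph.n_regions} (1-based); "
            f"found range {s.min()}..{s.max()}"
        )
    return s - 1


def _year_codes(data: pd.DataFrame) -> tuple[np.ndarray, list[int]]:
    years = sorted(int(y) for y in pd.unique(data["year"]))
    codes = pd.Categorical(data["year"].astype(int), categories=years).codes
    return np.asarray(codes, dtype=np.intp), years


def build_model_terms(
    data: pd.DataFrame,
    graph: AdjacencyGraph,
    model: str = "m6",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    references: dict[str, str] | None = None,
    n_interior_knots: int = 20,
    age_column: str = "mother_age",
) -> list[ModelTerm]:
    """Assemble the ModelTerm list for one model of the nested suite.

    Raises a schema error listing missing columns, and refuses a year smooth
    on single-year data (pointing at the starred variants instead).
    """
    if model not in _FEATURES:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_IDS}")
    feat = _FEATURES[model]
    refs = dict(DEFAULT_REFERENCES)
    refs.update(references or {})

    needed = {"fgm", "state"}
    if feat["year"] or feat["interaction"]:
        needed.add("year")
    if feat["survey"]:
        needed.add("survey")
    if feat["age"]:
        needed.add(age_column)
    if feat["covars"]:
        needed.update(covariates)
    missing = sorted(needed - set(data.columns))
    if missing:
        raise ValueError(f"data is missing required columns: {missing}")

    s_groups = _state_groups(data, graph)
    k_mrf = mrf_precision(graph)
    terms: list[ModelTerm] = []

    fixed_parts: list[ModelTerm] = []
    if feat["covars"]:
        for cov in covariates:
            if cov not in refs:
                raise ValueError(f"no reference level configured for covariate {cov!r}")
            fixed_parts.append(encode_categorical(data[cov], refs[cov], name=cov))
    if feat["survey"]:
        fixed_parts.append(encode_categorical(data["survey"], refs["survey"], name="survey"))
    if fixed_parts:
        terms.append(combine_fixed_terms(fixed_parts))
    else:
        n = len(data)
        terms.append(
            ModelTerm(
                name="fixed",
                kind="fixed",
                n_coef=1,
                X=np.ones((n, 1)),
                column_labels=["intercept"],
                components={"intercept": (slice(0, 1), ["intercept"], None)},
            )
        )

    if feat["age"]:
        _, x_age = bspline_basis(
            np.asarray(data[age_column], dtype=float), n_interior_knots=n_interior_knots
        )
        terms.append(
            ModelTerm(
                name="f(age)",
                kind="pspline",
                n_coef=x_age.shape[1],
                X=x_age,
                penalty=rw2_penalty(x_age.shape[1]),
            )
        )

    if feat["year"]:
        y_codes, years = _year_codes(data)
        if len(years) < 3:
            raise ValueError(
                f"only {len(years)} survey year(s) present: the year smooth needs "
                "at least 3; use the starred single-survey variants (m1*, m3*)"
            )
        terms.append(
            ModelTerm(
                name="f(year)",
                kind="pspline",
                n_coef=len(years),
                groups=y_codes,
                penalty=rw2_penalty(len(years)),
                column_labels=[str(y) for y in years],
            )
        )

    terms.append(
        ModelTerm(
            name="f_str",
            kind="mrf",
            n_coef=graph.n_regions,
            groups=s_groups,
            penalty=k_mrf,
            column_labels=list(graph.labels),
        )
    )
    terms.append(
        ModelTerm(
            name="f_unstr",
            kind="iid_region",
            n_coef=graph.n_regions,
            groups=s_groups,
            penalty=identity_penalty(graph.n_regions),
            column_labels=list(graph.labels),
        )
    )

    if feat["interaction"]:
        y_codes, years = _year_codes(data)
        t = len(years)
        cell = s_groups * t + y_codes
        n_cells = graph.n_regions * t
        labels = [f"{lab}:{yr}" for lab in graph.labels for yr in years]
        if feat["interaction"] == "iid":
            terms.append(
                ModelTerm(
                    name="xi",
                    kind="interaction_iid",
                    n_coef=n_cells,
                    groups=cell,
                    penalty=identity_penalty(n_cells),
                    column_labels=labels,
                )
            )
        else:
            if t < 3:
                raise ValueError("smooth space-time interaction needs at least 3 years")
            penalty = block_diag_penalty([rw2_penalty(t) for _ in range(graph.n_regions)], "rw2")
            terms.append(
                ModelTerm(
                    name="xi",
                    kind="interaction_smooth",
                    n_coef=n_cells,
                    groups=cell,
                    penalty=penalty,
                    column_labels=labels,
                )
            )
    return terms
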