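"""Additive model terms: design matrices, penalties, centring, dummy coding.

A :class:`ModelTerm` bundles one additive component f_j of the structured
additive predictor

    eta_i = z_i' omega + f_1(x_i1) + ... + f_str(s_i) + f_unstr(s_i) + xi

with its design matrix X_j, penalty K_j and the hyperparameter slot for the
smoothing variance tau_j^2.  Fixed-effect blocks carry no penalty (flat
prior); every penalised block's fitted values are kept centred on zero for
identifiability, with the removed mean absorbed into the global intercept.

Two design representations are used:

* dense ``X`` (splines, dummy-coded fixed effects);
* ``groups`` — an integer label per observation for purely categorical
  designs (region, year, space-time cell), where X is an indicator matrix
  and cross-products reduce to ``bincount`` calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .penalties import PenaltyMatrix

__all__ = ["ModelTerm", "encode_categorical", "combine_fixed_terms", "apply_centering"]

TERM_KINDS = (
    "fixed",
    "pspline",
    "mrf",
    "iid_region",
    "interaction_smooth",
    "interaction_iid",
)


@dataclass
class ModelTerm:
    name: str
    kind: str
    n_coef: int
    X: np.ndarray | None = None
    groups: np.ndarray | None = None
    penalty: PenaltyMatrix | None = None
    reference_level: str | None = None
    column_labels: list[str] | None = None
    # fixed blocks assembled from several covariates: covariate -> (slice, levels, ref)
    components: dict[str, tuple[slice, list[str], str | None]] = field(default_factory=dict)
    a: float = 1.0
    b: float = 0.0005

    def __post_init__(self) -> None:
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if (self.X is None) == (self.groups is None):
            raise ValueError("exactly one of X or groups must be given")
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.shape[1] != self.n_coef:
                raise ValueError("design column count does not match n_coef")
        else:
            self.groups = np.asarray(self.groups, dtype=np.intp)
            if self.groups.min() < 0 or self.groups.max() >= self.n_coef:
                raise ValueError("group index out of range")
        if self.kind == "fixed":
            if self.penalty is not None:
                raise ValueError("fixed blocks take a flat prior (no penalty)")
        else:
            if self.penalty is None:
                raise ValueError(f"{self.kind} term needs a penalty")
            if self.penalty.dim != self.n_coef:
                raise ValueError("penalty dimension does not match design columns")

    # -- design products -------------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.groups) if self.groups is not None else self.X.shape[0]

    def fitted(self, beta: np.ndarray) -> np.ndarray:
        """f_j = X_j beta_j."""
        if self.groups is not None:
            return beta[self.groups]
        return self.X @ beta

    def xtv(self, v: np.ndarray) -> np.ndarray:
        """X_j' v."""
        if self.groups is not None:
            return np.bincount(self.groups, weights=v, minlength=self.n_coef)
        return self.X.T @ v

    def xtwx(self, w: np.ndarray) -> np.ndarray:
        """X_j' diag(w) X_j."""
        if self.groups is not None:
            return np.diag(np.bincount(self.groups, weights=w, minlength=self.n_coef))
        return self.X.T @ (self.X * w[:, None])

    @property
    def rows_sum_to_one(self) -> bool:
        """True for indicator and partition-of-unity designs (centring relies on it)."""
        if self.groups is not None:
            return True
        return bool(np.allclose(self.X.sum(axis=1), 1.0, atol=1e-8))


def encode_categorical(column, reference: str, name: str | None = None) -> ModelTerm:
    """Dummy-code a categorical covariate against a stated reference level.

    One indicator column per non-reference level (treatment contrasts), so
    exp(beta) reads directly as an odds ratio against the reference — the
    convention used for posterior odds-ratio tables.
    """
    col = pd.Series(column).astype(str)
    name = name or (col.name if col.name is not None else "covariate")
    levels = sorted(col.unique())
    reference = str(reference)
    if reference not in levels:
        raise ValueError(
            f"reference level {reference!r} not found in {name!r}; observed levels: {levels}"
        )
    others = [l for l in levels if l != reference]
    x = np.column_stack([(col == l).to_numpy(dtype=float) for l in others]) if others else np.empty((len(col), 0))
    return ModelTerm(
        name=name,
        kind="fixed",
        n_coef=len(others),
        X=x,
        reference_level=reference,
        column_labels=[f"{name}:{l}" for l in others],
        components={name: (slice(0, len(others)), levels, reference)},
    )


def combine_fixed_terms(terms: list[ModelTerm], add_intercept: bool = True) -> ModelTerm:
    """Stack fixed-effect covariate blocks (plus an intercept) into one block.

    All fixed effects are updated jointly in the sampler; the per-covariate
    column spans are retained so odds-ratio tables can be split back out.
    """
    if any(t.kind != "fixed" for t in terms):
        raise ValueError("only fixed terms can be combined")
    if not terms and not add_intercept:
        raise ValueError("empty fixed block")
    n = terms[0].n_obs if terms else None
    mats: list[np.ndarray] = []
    labels: list[str] = []
    components: dict[str, tuple[slice, list[str], str | None]] = {}
    offset = 0
    if add_intercept:
        if n is None:
            raise ValueError("cannot infer n for intercept-only block without terms")
        mats.append(np.ones((n, 1)))
        labels.append("intercept")
        components["intercept"] = (slice(0, 1), ["intercept"], None)
        offset = 1
    for t in terms:
        mats.append(t.X)
        labels.extend(t.column_labels or [])
        (covname, (_, levels, ref)), = t.components.items()
        if covname in components:
            raise ValueError(f"duplicate fixed covariate {covname!r}")
        components[covname] = (slice(offset, offset + t.n_coef), levels, ref)
        offset += t.n_coef
    x = np.hstack(mats)
    return ModelTerm(
        name="fixed",
        kind="fixed",
        n_coef=x.shape[1],
        X=x,
        column_labels=labels,
        components=components,
    )


def apply_centering(term: ModelTerm, beta: np.ndarray) -> tuple[np.ndarray, float]:
    """Centre a penalised term's fitted values; return (new beta, intercept shift).

    The empirical mean c of X_j beta_j over the observed rows is subtracted
    from every coefficient (valid because all penalised designs here have
    rows summing to one) and returned so the caller can add c to the global
    intercept — the linear predictor is unchanged.
    """
    if term.kind == "fixed":
        raise ValueError("fixed blocks are not centred")
    if not term.rows_sum_to_one:
        raise ValueError("centring by coefficient shift needs row sums of one")
    c = float(np.mean(term.fitted(beta)))
    return beta - c, c
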