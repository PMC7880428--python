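"""Metropolis-Hastings sampler with IWLS proposals for the geo-additive logit.

Each additive block beta_j is updated by a Gamerman-style move: the Gaussian
proposal N(m_j, P_j^{-1}) is the one-step iteratively-weighted-least-squares
approximation of the full conditional at the current state,

    P_j = X_j' W X_j + K_j / tau_j^2,
    m_j = P_j^{-1} X_j' W (ytilde - eta_{-j}),

with W = diag(p(1-p)) and working response ytilde = eta + (y - p)/W; the
proposal density is re-derived at the proposed state for the reverse move
and the exact Bernoulli likelihood enters the acceptance ratio.  Smoothing
variances tau_j^2 are Gibbs-updated from their conjugate inverse-gamma full
conditional IG(a + rank(K_j)/2, b + beta_j' K_j beta_j / 2).

After every accepted (or retained) update of a penalised block its fitted
values are re-centred on zero and the mean absorbed into the intercept —
the standard identifiability convention for intrinsic spatial priors and
paired structured/unstructured effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import expit

from .terms import ModelTerm, apply_centering

__all__ = ["MCMCConfig", "PosteriorSamples", "iwls_quantities", "update_variance", "run_mcmc"]

logger = logging.getLogger(__name__)

IWLS_WEIGHT_FLOOR = 1e-6


@dataclass
class MCMCConfig:
    """Sampler schedule and hyperpriors.

    Defaults mirror the application's schedule: 20,000 iterations, the first
    4,000 discarded as burn-in (leaving 16,000), thinned to every 20th draw
    (800 stored), with diffuse IG(1, 0.0005) hyperpriors on all smoothing
    variances.
    """

    n_iter: int = 20000
    burn_in: int = 4000
    thin: int = 20
    a: float = 1.0
    b: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")

    @property
    def n_kept(self) -> int:
        """Post-burn-in draws before thinning."""
        return self.n_iter - self.burn_in

    @property
    def n_retained(self) -> int:
        """Stored draws after thinning."""
        return self.n_kept // self.thin


@dataclass
class PosteriorSamples:
    """Retained draws plus enough metadata to reconstruct linear predictors."""

    terms: list[ModelTerm]
    coef: dict[str, np.ndarray]  # name -> (n_draws, n_coef)
    tau2: dict[str, np.ndarray]  # name -> (n_draws,)
    acceptance: dict[str, float]
    config: MCMCConfig
    _eta_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_draws(self) -> int:
        return next(iter(self.coef.values())).shape[0]

    def term(self, name: str) -> ModelTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def linear_predictors(self) -> np.ndarray:
        """(n_draws, n_obs) matrix of eta reconstructed from the stored draws."""
        if self._eta_cache is None:
            n = self.terms[0].n_obs
            eta = np.zeros((self.n_draws, n))
            for t in self.terms:
                b = self.coef[t.name]
                if t.groups is not None:
                    eta += b[:, t.groups]
                else:
                    eta += b @ t.X.T
            self._eta_cache = eta
        return self._eta_cache


def iwls_quantities(y: np.ndarray, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Working response and weights of the Bernoulli-logit IWLS step.

    w = p(1-p) floored at 1e-6 for numerical stability at extreme eta;
    ytilde = eta + (y - p) / w.
    """
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    p = expit(eta)
    w = np.maximum(p * (1.0 - p), IWLS_WEIGHT_FLOOR)
    return eta + (np.asarray(y) - p) / w, w


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Exact log-likelihood sum(y*eta - log(1 + e^eta)), numerically stable."""
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def _chol_with_jitter(p: np.ndarray) -> np.ndarray:
    """Clean lower-triangular Cholesky factor, jittering a singular precision."""
    scale = float(np.mean(np.diag(p))) or 1.0
    jitter = 0.0
    for _ in range(6):
        try:
            return np.linalg.cholesky(p + jitter * np.eye(p.shape[0]))
        except np.linalg.LinAlgError:
            jitter = 1e-10 * scale if jitter == 0.0 else jitter * 100
            logger.warning("singular proposal precision; adding jitter %.3g", jitter)
    raise np.linalg.LinAlgError("proposal precision not positive definite even with jitter")


def _proposal(term: ModelTerm, y, eta, eta_rest, tau2):
    """IWLS proposal (m, chol P, logdet P) for one block at the given state."""
    ytilde, w = iwls_quantities(y, eta)
    p = term.xtwx(w)
    if term.penalty is not None:
        p = p + term.penalty.matrix / tau2
    chol = _chol_with_jitter(p)
    m = cho_solve((chol, True), term.xtv(w * (ytilde - eta_rest)))
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return m, chol, logdet


def _log_q(beta, m, chol, logdet) -> float:
    d = beta - m
    # P = L L'; d'Pd = ||L' d||^2
    u = chol.T @ d
    return 0.5 * logdet - 0.5 * float(u @ u)


def _log_prior(term: ModelTerm, beta, tau2) -> float:
    if term.penalty is None:
        return 0.0
    return -0.5 * term.penalty.quad_form(beta) / tau2


def update_coefficient_block(
    term: ModelTerm,
    beta: np.ndarray,
    tau2: float,
    y: np.ndarray,
    eta: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One MH step for a block; returns (beta, eta, accepted)."""
    f_cur = term.fitted(beta)
    eta_rest = eta - f_cur

    m, chol, logdet = _proposal(term, y, eta, eta_rest, tau2)
    z = rng.standard_normal(term.n_coef)
    # draw from N(m, P^{-1}) via L' x = z
    beta_prop = m + solve_triangular(chol, z, lower=True, trans="T")
    eta_prop = eta_rest + term.fitted(beta_prop)

    m_rev, chol_rev, logdet_rev = _proposal(term, y, eta_prop, eta_rest, tau2)

    log_alpha = (
        bernoulli_loglik(y, eta_prop)
        + _log_prior(term, beta_prop, tau2)
        + _log_q(beta, m_rev, chol_rev, logdet_rev)
        - bernoulli_loglik(y, eta)
        - _log_prior(term, beta, tau2)
        - _log_q(beta_prop, m, chol, logdet)
    )
    if np.log(rng.random()) < log_alpha:
        return beta_prop, eta_prop, True
    return beta, eta, False


def update_variance(
    beta: np.ndarray,
    penalty,
    a: float,
    b: float,
    rng: np.random.Generator,
) -> float:
    """Gibbs draw of tau^2 from IG(a + rank(K)/2, b + beta'K beta/2)."""
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    shape = a + penalty.rank / 2.0
    scale = b + penalty.quad_form(np.asarray(beta)) / 2.0
    return float(scale / rng.gamma(shape))


def run_mcmc(
    y,
    terms: list[ModelTerm],
    config: MCMCConfig | None = None,
    verbose: bool = False,
) -> PosteriorSamples:
    """Run the block sampler over all terms.

    Per iteration: every coefficient block is MH-updated in a fixed order
    (the fixed block first, then the terms as given), penalised blocks are
    re-centred with the mean pushed into the intercept, and each smoothing
    variance is Gibbs-updated.  Draws after burn-in are stored every
    ``thin``-th iteration.
    """
    cfg = config or MCMCConfig()
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    for t in terms:
        if t.n_obs != n:
            raise ValueError(f"term {t.name!r} has {t.n_obs} rows, data has {n}")
    names = [t.name for t in terms]
    if len(set(names)) != len(names):
        raise ValueError("duplicate term names")
    fixed = [t for t in terms if t.kind == "fixed"]
    if len(fixed) != 1 or "intercept" not in (fixed[0].column_labels or []):
        raise ValueError("exactly one fixed block containing an intercept is required")
    ordered = fixed + [t for t in terms if t.kind != "fixed"]
    icol = fixed[0].column_labels.index("intercept")

    rng = np.random.default_rng(cfg.seed)
    beta = {t.name: np.zeros(t.n_coef) for t in ordered}
    tau2 = {t.name: 0.1 for t in ordered if t.penalty is not None}
    eta = np.zeros(n)
    accepted = {t.name: 0 for t in ordered}

    coef_draws: dict[str, list[np.ndarray]] = {t.name: [] for t in ordered}
    tau2_draws: dict[str, list[float]] = {nm: [] for nm in tau2}

    for it in range(cfg.n_iter):
        for t in ordered:
            b_new, eta, acc = update_coefficient_block(
                t, beta[t.name], tau2.get(t.name, np.inf), y, eta, rng
            )
            beta[t.name] = b_new
            accepted[t.name] += acc
            if t.kind != "fixed":
                b_c, shift = apply_centering(t, beta[t.name])
                if shift != 0.0:
                    beta[t.name] = b_c
                    beta["fixed"] = beta["fixed"].copy()
                    beta["fixed"][icol] += shift
                    # eta is unchanged by construction
        for nm in tau2:
            t = next(tt for tt in ordered if tt.name == nm)
            tau2[nm] = update_variance(beta[nm], t.penalty, cfg.a, cfg.b, rng)
        if not np.all(np.isfinite(eta)):
            raise FloatingPointError(f"non-finite linear predictor at iteration {it}")
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == cfg.thin - 1:
            for nm in coef_draws:
                coef_draws[nm].append(beta[nm].copy())
            for nm in tau2:
                tau2_draws[nm].append(tau2[nm])
        if verbose and (it + 1) % max(cfg.n_iter // 10, 1) == 0:
            logger.info("iteration %d/%d", it + 1, cfg.n_iter)

    return PosteriorSamples(
        terms=ordered,
        coef={nm: np.vstack(v) for nm, v in coef_draws.items()},
        tau2={nm: np.asarray(v) for nm, v in tau2_draws.items()},
        acceptance={nm: accepted[nm] / cfg.n_iter for nm in accepted},
        config=cfg,
    )
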