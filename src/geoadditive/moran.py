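"""Global Moran's I spatial autocorrelation on a contiguity graph.

Binary (unstandardised) contiguity weights throughout: w_rs = 1 iff regions
r and s share a border.  A significantly positive I indicates clustering of
like values among neighbours; a significantly negative I indicates
dispersion (checkerboard structure).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .graph import AdjacencyGraph

__all__ = ["morans_i", "morans_i_test"]


def _centered(values, graph: AdjacencyGraph) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size != graph.n_regions:
        raise ValueError(
            f"need one value per region ({graph.n_regions}), got shape {v.shape}"
        )
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    z = v - v.mean()
    if np.allclose(z, 0.0):
        raise ValueError("values are constant: Moran's I is undefined (zero variance)")
    return z


def morans_i(values, graph: AdjacencyGraph) -> float:
    """I = (S / W0) * sum_{r,s} w_rs z_r z_s / sum_r z_r^2 with centred z."""
    z = _centered(values, graph)
    w = graph.adjacency_matrix()
    w0 = w.sum()
    if w0 == 0:
        raise ValueError("graph has no edges")
    return float(graph.n_regions / w0 * (z @ w @ z) / (z @ z))


def _analytic_null(graph: AdjacencyGraph) -> tuple[float, float]:
    """Null mean and variance of I under the normality assumption."""
    s = graph.n_regions
    w = graph.adjacency_matrix()
    w0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()
    e_i = -1.0 / (s - 1)
    var = (s * s * s1 - s * s2 + 3.0 * w0 * w0) / (w0 * w0 * (s * s - 1.0)) - e_i**2
    return e_i, var


def morans_i_test(
    values,
    graph: AdjacencyGraph,
    method: str = "analytic",
    n_sims: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Moran's I with a p-value, analytic (normal approximation) or permutation.

    Parameters
    ----------
    method
        ``analytic``: z-score against the null mean -1/(S-1) and the
        normality-assumption variance. ``monte_carlo``: random permutations of
        the region values; p = (1 + #{I_sim >= I_obs}) / (n_sims + 1), so the
        estimate never returns exactly zero.
    alternative
        ``greater`` (clustering, default), ``less`` (dispersion) or
        ``two_sided``.
    """
    i_obs = morans_i(values, graph)
    if method == "analytic":
        e_i, var = _analytic_null(graph)
        zscore = (i_obs - e_i) / math.sqrt(var)
        if alternative == "greater":
            p = stats.norm.sf(zscore)
        elif alternative == "less":
            p = stats.norm.cdf(zscore)
        elif alternative == "two_sided":
            p = 2.0 * stats.norm.sf(abs(zscore))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return i_obs, float(p)
    if method == "monte_carlo":
        if n_sims < 99:
            raise ValueError("monte_carlo needs n_sims >= 99")
        rng = np.random.default_rng(seed)
        v = np.asarray(values, dtype=float)
        sims = np.empty(n_sims)
        for k in range(n_sims):
            sims[k] = morans_i(rng.permutation(v), graph)
        if alternative == "greater":
            extreme = int((sims >= i_obs).sum())
        elif alternative == "less":
            extreme = int((sims <= i_obs).sum())
        elif alternative == "two_sided":
            e_i = -1.0 / (graph.n_regions - 1)
            extreme = int((np.abs(sims - e_i) >= abs(i_obs - e_i)).sum())
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return i_obs, (1.0 + extreme) / (n_sims + 1.0)
    raise ValueError(f"unknown method {method!r}; use 'analytic' or 'monte_carlo'")
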