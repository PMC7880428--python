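"""Penalty (prior precision) matrices for the additive model terms.

Every penalised term carries a symmetric positive semidefinite matrix K whose
quadratic form beta' K beta appears in the Gaussian smoothing prior
pi(beta | tau^2) ∝ (tau^2)^(-rank(K)/2) exp(-beta' K beta / (2 tau^2)).
The three kinds used here:

* ``mrf`` — intrinsic conditional-autoregressive precision on a region graph
  (diagonal = neighbour counts, off-diagonal -1 for contiguous pairs);
* ``rw2`` — second-order random-walk penalty, K = D2' D2 with D2 the
  second-difference operator, penalising curvature of spline/step functions;
* ``identity`` — exchangeable (iid) random-effect penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PenaltyMatrix", "rw2_penalty", "identity_penalty", "block_diag_penalty"]

_KINDS = ("mrf", "rw2", "identity")


@dataclass(frozen=True)
class PenaltyMatrix:
    """A symmetric PSD penalty with its rank and structural kind."""

    matrix: np.ndarray
    rank: int
    kind: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("penalty matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("penalty matrix must be symmetric")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown penalty kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind in ("mrf", "rw2") and not np.allclose(m.sum(axis=1), 0.0, atol=1e-8):
            raise ValueError(f"{self.kind} penalty rows must sum to zero")
        object.__setattr__(self, "matrix", m)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def quad_form(self, beta: np.ndarray) -> float:
        """beta' K beta (clipped at zero against roundoff)."""
        q = float(np.asarray(beta) @ self.matrix @ np.asarray(beta))
        if q < -1e-8 * max(1.0, abs(q)):
            raise AssertionError("negative quadratic form: penalty is not PSD")
        return max(q, 0.0)


def rw2_penalty(m: int) -> PenaltyMatrix:
    """Second-order random-walk penalty K = D2' D2 on ``m`` coefficients.

    The null space is spanned by constant and linear sequences, so
    rank(K) = m - 2, and beta' K beta equals the sum of squared second
    differences of beta.
    """
    if m < 3:
        raise ValueError("RW2 penalty needs at least 3 coefficients")
    d2 = np.diff(np.eye(m), n=2, axis=0)
    return PenaltyMatrix(matrix=d2.T @ d2, rank=m - 2, kind="rw2")


def identity_penalty(m: int) -> PenaltyMatrix:
    """Full-rank iid (exchangeable) random-effect penalty."""
    if m < 1:
        raise ValueError("need at least one coefficient")
    return PenaltyMatrix(matrix=np.eye(m), rank=m, kind="identity")


def block_diag_penalty(blocks: list[PenaltyMatrix], kind: str) -> PenaltyMatrix:
    """Assemble a block-diagonal penalty (e.g. one RW2 block per region)."""
    from scipy.linalg import block_diag

    mat = block_diag(*[b.matrix for b in blocks])
    return PenaltyMatrix(matrix=mat, rank=sum(b.rank for b in blocks), kind=kind)
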