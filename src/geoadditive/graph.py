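"""Region adjacency graphs and the intrinsic Markov-random-field prior.

An :class:`AdjacencyGraph` records which administrative regions share a
border.  The contiguity structure drives two things downstream:

* the intrinsic Gaussian MRF (ICAR) prior on the structured spatial effect,
  whose precision is the graph Laplacian scaled by 1/tau^2 — conditionally,
  each region effect is normal around the mean of its neighbours with
  variance tau^2 / N_s;
* Moran's I tests of spatial clustering (see :mod:`geoadditive.moran`).

Two text dialects are supported: a plain edge list (two labels per line) and
a ``.gra`` region file (first line the region count; then, per region, a
label line, a neighbour-count line and a line of 1-based neighbour indices).
Region indices are 1-based in files and 0-based in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .penalties import PenaltyMatrix

__all__ = ["AdjacencyGraph", "read_graph", "write_graph", "mrf_precision", "sample_igmrf"]


class GraphFormatError(ValueError):
    """Raised for malformed adjacency files (asymmetry, self-loops, bad indices)."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected contiguity graph over labelled regions.

    Parameters
    ----------
    labels
        Ordered region identifiers; position defines the 0-based index.
    edges
        Unordered pairs of 0-based indices, stored as (i, j) with i < j.
    """

    labels: tuple[str, ...]
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        if len(set(labels)) != len(labels):
            raise GraphFormatError("duplicate region labels")
        n = len(labels)
        norm = set()
        for (i, j) in self.edges:
            if i == j:
                raise GraphFormatError(f"self-loop on region {labels[i]!r}")
            if not (0 <= i < n and 0 <= j < n):
                raise GraphFormatError(f"edge ({i}, {j}) out of range for {n} regions")
            norm.add((min(i, j), max(i, j)))
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "edges", frozenset(norm))

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def neighbor_counts(self) -> np.ndarray:
        """Per-region number of contiguous neighbours N_s."""
        counts = np.zeros(self.n_regions, dtype=int)
        for i, j in self.edges:
            counts[i] += 1
            counts[j] += 1
        return counts

    def neighbors(self, s: int) -> list[int]:
        return sorted({j if i == s else i for i, j in self.edges if s in (i, j)})

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 contiguity matrix."""
        w = np.zeros((self.n_regions, self.n_regions))
        for i, j in self.edges:
            w[i, j] = w[j, i] = 1.0
        return w

    @property
    def n_components(self) -> int:
        if not self.edges:
            return self.n_regions
        rows, cols = zip(*self.edges)
        a = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.n_regions, self.n_regions)
        )
        ncomp, _ = connected_components(a, directed=False)
        return int(ncomp)

    @property
    def is_connected(self) -> bool:
        return self.n_components == 1

    def index_of(self, label: str) -> int:
        return self.labels.index(str(label))


def read_graph(path: str | Path, dialect: str = "edge_list") -> AdjacencyGraph:
    """Read an adjacency graph from ``path`` in the named dialect."""
    text = Path(path).read_text()
    if dialect == "edge_list":
        return _parse_edge_list(text)
    if dialect == "gra":
        return _parse_gra(text)
    raise ValueError(f"unknown graph dialect {dialect!r}")


def _parse_edge_list(text: str) -> AdjacencyGraph:
    labels: list[str] = []
    index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphFormatError(f"line {lineno}: expected two labels, got {line!r}")
        idx = []
        for lab in parts:
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
            idx.append(index[lab])
        if idx[0] == idx[1]:
            raise GraphFormatError(f"line {lineno}: self-loop on region {parts[0]!r}")
        edges.add((min(idx), max(idx)))
    return AdjacencyGraph(labels=tuple(labels), edges=frozenset(edges))


def _parse_gra(text: str) -> AdjacencyGraph:
    lines = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
    if not lines:
        raise GraphFormatError("empty .gra file")
    try:
        n = int(lines[0])
    except ValueError as exc:
        raise GraphFormatError("first .gra line must be the region count") from exc
    if len(lines) != 1 + 3 * n:
        raise GraphFormatError(
            f".gra file should have 1 + 3*{n} = {1 + 3 * n} lines, found {len(lines)}"
        )
    labels: list[str] = []
    neigh: list[list[int]] = []
    for r in range(n):
        label = lines[1 + 3 * r]
        count = int(lines[2 + 3 * r])
        row = lines[3 + 3 * r]
        ids = [int(t) for t in row.split()] if count > 0 else []
        if count == 0 and row not in ("", "-"):
            # allow an explicit empty marker; anything else is a count mismatch
            ids = [int(t) for t in row.split()]
        if len(ids) != count:
            raise GraphFormatError(
                f"region {label!r}: neighbour count {count} but {len(ids)} indices listed"
            )
        for k in ids:
            if not (1 <= k <= n):
                raise GraphFormatError(f"region {label!r}: neighbour index {k} out of range 1..{n}")
            if k == r + 1:
                raise GraphFormatError(f"region {label!r}: self-loop")
        labels.append(label)
        neigh.append([k - 1 for k in ids])
    for s, ns in enumerate(neigh):
        for r in ns:
            if s not in neigh[r]:
                raise GraphFormatError(
                    f"asymmetric neighbour lists: {labels[s]!r} lists {labels[r]!r} "
                    f"but not vice versa"
                )
    edges = {(min(s, r), max(s, r)) for s, ns in enumerate(neigh) for r in ns}
    return AdjacencyGraph(labels=tuple(labels), edges=frozenset(edges))


def write_graph(graph: AdjacencyGraph, path: str | Path, dialect: str = "edge_list") -> None:
    """Write ``graph`` losslessly in the named dialect (isolated regions need .gra)."""
    path = Path(path)
    if dialect == "edge_list":
        if any(c == 0 for c in graph.neighbor_counts):
            raise ValueError("edge-list dialect cannot represent isolated regions; use 'gra'")
        lines = [
            f"{graph.labels[i]} {graph.labels[j]}" for i, j in sorted(graph.edges)
        ]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "gra":
        out = [str(graph.n_regions)]
        for s, label in enumerate(graph.labels):
            ns = graph.neighbors(s)
            out.append(label)
            out.append(str(len(ns)))
            out.append(" ".join(str(r + 1) for r in ns) if ns else "-")
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unknown graph dialect {dialect!r}")


def mrf_precision(graph: AdjacencyGraph) -> PenaltyMatrix:
    """Intrinsic-CAR precision: diag(N_s) minus the contiguity matrix.

    Rows sum to zero; beta' K beta = sum over contiguous pairs of
    (beta_r - beta_s)^2; rank is S minus the number of connected components.
    """
    w = graph.adjacency_matrix()
    k = np.diag(graph.neighbor_counts.astype(float)) - w
    return PenaltyMatrix(matrix=k, rank=graph.n_regions - graph.n_components, kind="mrf")


def sample_igmrf(
    graph: AdjacencyGraph,
    tau2: float,
    n_draws: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw sum-to-zero vectors from the intrinsic GMRF with precision K/tau2.

    The intrinsic prior is improper (K is rank S-1 on a connected graph); we
    sample on the orthogonal complement of the constant vector via the
    spectral decomposition of K, which makes every draw sum to zero exactly —
    the same zero-centring convention used to identify the structured spatial
    effect in the model.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    if not graph.is_connected:
        raise ValueError(
            "graph is disconnected: the intrinsic GMRF needs a sum-to-zero "
            "constraint per connected component; supply a connected graph or "
            "sample each component separately"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    k = mrf_precision(graph).matrix
    eigval, eigvec = np.linalg.eigh(k)
    tol = 1e-9 * max(eigval.max(), 1.0)
    keep = eigval > tol
    if (~keep).sum() != 1:
        raise ValueError("expected exactly one null eigenvalue on a connected graph")
    lam = eigval[keep]
    v = eigvec[:, keep]
    z = rng.standard_normal((n_draws, lam.size))
    draws = (z / np.sqrt(lam)) @ v.T * np.sqrt(tau2)
    return draws - draws.mean(axis=1, keepdims=True)
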