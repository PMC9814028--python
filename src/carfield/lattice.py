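"""Areal adjacency structures for disease mapping.

A map of ``n`` contiguous areas is represented by its binary, symmetric
neighbourhood matrix ``W`` (``w_ik = 1`` iff areas ``i`` and ``k`` share a
border) together with the neighbour counts ``w_i+`` and their diagonal
matrix ``D_w``.  Every conditional autoregressive prior in this package is
built from the structure matrix ``Q(c) = D_w - c W``.

Indexing convention: files use 1-based area identifiers (the convention of
GeoBUGS adjacency exports); everything in memory is 0-based.  The readers
and writers in this module are the only places where translation happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "NeighborOrders",
    "AdjacencyError",
    "build_grid",
    "read_adjacency",
    "write_adjacency",
    "neighbor_orders",
    "structure_matrix",
]


class AdjacencyError(ValueError):
    """Raised for malformed adjacency input (self-loops, bad indices...)."""


@dataclass(frozen=True, eq=False)
class AdjacencyGraph:
    """Symmetric areal adjacency structure.

    Attributes
    ----------
    n : int
        Number of areas.
    edges : frozenset of (int, int)
        Unordered neighbour pairs, stored as ``(i, k)`` with ``i < k``,
        0-based.
    W : scipy.sparse.csr_matrix
        Binary symmetric neighbourhood matrix with zero diagonal.
    wplus : numpy.ndarray
        Per-area neighbour counts ``w_i+`` (row sums of ``W``).
    """

    n: int
    edges: frozenset = field(repr=False)
    W: sp.csr_matrix = field(repr=False)
    wplus: np.ndarray = field(repr=False)

    @property
    def Dw(self) -> sp.dia_matrix:
        """Diagonal matrix of neighbour counts."""
        return sp.diags(self.wplus.astype(float))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def is_connected(self) -> bool:
        ncomp, _ = connected_components(self.W, directed=False)
        return bool(ncomp == 1)

    @property
    def has_islands(self) -> bool:
        """True if any area has no neighbours (``w_i+ = 0``)."""
        return bool(np.any(self.wplus == 0))

    def validate(self) -> None:
        W = self.W
        if (W != W.T).nnz != 0:
            raise AdjacencyError("W must be symmetric")
        if W.diagonal().any():
            raise AdjacencyError("W must have a zero diagonal")
        data = W.data
        if data.size and not np.all(data == 1):
            raise AdjacencyError("W entries must be 0 or 1 (binary adjacency)")
        if not np.array_equal(self.wplus, np.asarray(W.sum(axis=1)).ravel()):
            raise AdjacencyError("wplus inconsistent with row sums of W")


def _graph_from_edges(n: int, edges) -> AdjacencyGraph:
    edges = frozenset((min(i, k), max(i, k)) for i, k in edges)
    if edges:
        ii, kk = map(np.asarray, zip(*sorted(edges)))
        rows = np.concatenate([ii, kk])
        cols = np.concatenate([kk, ii])
        W = sp.csr_matrix(
            (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n)
        )
    else:
        W = sp.csr_matrix((n, n), dtype=np.int8)
    wplus = np.asarray(W.sum(axis=1)).ravel().astype(np.int64)
    g = AdjacencyGraph(n=n, edges=edges, W=W, wplus=wplus)
    g.validate()
    return g


def build_grid(nrows: int, ncols: int, rule: str = "rook") -> AdjacencyGraph:
    """Regular lattice with rook (4-) or queen (8-) neighbourhoods.

    A convenient synthetic stand-in for county maps in simulation studies.
    """
    if nrows < 1 or ncols < 1:
        raise ValueError("grid dimensions must be positive")
    if nrows * ncols < 2:
        raise ValueError("grid must contain at least 2 areas")
    if rule not in ("rook", "queen"):
        raise ValueError(f"unknown neighbourhood rule {rule!r}")
    steps = [(0, 1), (1, 0)]
    if rule == "queen":
        steps += [(1, 1), (1, -1)]
    edges = []
    for r in range(nrows):
        for c in range(ncols):
            i = r * ncols + c
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    edges.append((i, rr * ncols + cc))
    return _graph_from_edges(nrows * ncols, edges)


def _parse_edge_list(lines) -> tuple[int, list]:
    edges = []
    seen = set()
    max_idx = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise AdjacencyError(f"line {lineno}: expected 'i k', got {raw!r}")
        try:
            i, k = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise AdjacencyError(f"line {lineno}: non-integer index") from exc
        if i == k:
            raise AdjacencyError(f"line {lineno}: self-loop on area {i}")
        if i < 1 or k < 1:
            raise AdjacencyError(f"line {lineno}: indices must be >= 1")
        key = (min(i, k), max(i, k))
        if key in seen:
            raise AdjacencyError(f"line {lineno}: duplicate edge {i} {k}")
        seen.add(key)
        max_idx = max(max_idx, i, k)
        edges.append((i - 1, k - 1))
    return max_idx, edges


def _parse_bugs_adj(text: str) -> tuple[int, list]:
    """GeoBUGS-style layout: vector ``num`` (length n) then ``adj``.

    Accepts either ``num = c(...)`` / ``adj = c(...)`` assignments or two
    whitespace-separated integer blocks separated by a blank line.
    """
    import re

    nums = re.findall(r"num\s*=?\s*c?\(([^)]*)\)", text)
    adjs = re.findall(r"adj\s*=?\s*c?\(([^)]*)\)", text)
    if nums and adjs:
        num = [int(t) for t in re.split(r"[\s,]+", nums[0].strip()) if t]
        adj = [int(t) for t in re.split(r"[\s,]+", adjs[0].strip()) if t]
    else:
        blocks = [b for b in re.split(r"\n\s*\n", text) if b.strip()]
        if len(blocks) < 2:
            raise AdjacencyError(
                "bugs_adj needs num=(...) adj=(...) or two blank-line-separated blocks"
            )
        num = [int(t) for t in blocks[0].split()]
        adj = [int(t) for t in blocks[1].split()]
    n = len(num)
    if sum(num) != len(adj):
        raise AdjacencyError(
            f"adj has length {len(adj)} but num sums to {sum(num)}"
        )
    edges = set()
    directed = set()
    pos = 0
    for i, ni in enumerate(num):
        for k in adj[pos : pos + ni]:
            if not 1 <= k <= n:
                raise AdjacencyError(
                    f"area {i + 1}: neighbour index {k} outside 1..{n}"
                )
            if k - 1 == i:
                raise AdjacencyError(f"area {i + 1}: self-loop")
            directed.add((i, k - 1))
            edges.add((min(i, k - 1), max(i, k - 1)))
        pos += ni
    asym = [(i, k) for i, k in directed if (k, i) not in directed]
    if asym:
        logger.warning(
            "bugs_adj listing is asymmetric for %d pair(s); symmetrizing", len(asym)
        )
    return n, sorted(edges)


def read_adjacency(path, dialect: str = "edge_list", n: int | None = None) -> AdjacencyGraph:
    """Read an adjacency structure from a text file.

    Parameters
    ----------
    path : path-like
    dialect : {"edge_list", "bugs_adj"}
        ``edge_list`` is one whitespace/comma-delimited 1-based pair per
        line with ``#`` comments; ``bugs_adj`` is the GeoBUGS (num, adj)
        vector convention.
    n : int, optional
        Total number of areas (edge_list only); defaults to the largest
        index seen, so pass it explicitly if trailing areas are isolated.
    """
    text = Path(path).read_text()
    if dialect == "edge_list":
        max_idx, edges = _parse_edge_list(text.splitlines())
        n_areas = n if n is not None else max_idx
        if max_idx > (n_areas or 0):
            raise AdjacencyError(f"edge index {max_idx} exceeds declared n={n_areas}")
        if n_areas < 2:
            raise AdjacencyError("adjacency file defines fewer than 2 areas")
        return _graph_from_edges(n_areas, edges)
    if dialect == "bugs_adj":
        n_areas, edges = _parse_bugs_adj(text)
        return _graph_from_edges(n_areas, edges)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_adjacency(graph: AdjacencyGraph, path, dialect: str = "edge_list") -> None:
    """Write a graph back out in one of the supported text dialects."""
    path = Path(path)
    if dialect == "edge_list":
        lines = [f"{i + 1} {k + 1}" for i, k in sorted(graph.edges)]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "bugs_adj":
        nbrs = [[] for _ in range(graph.n)]
        for i, k in sorted(graph.edges):
            nbrs[i].append(k + 1)
            nbrs[k].append(i + 1)
        num = " ".join(str(len(b)) for b in nbrs)
        adj = " ".join(str(k) for b in nbrs for k in sorted(b))
        path.write_text(f"num = c({num})\nadj = c({adj})\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


@dataclass(frozen=True, eq=False)
class NeighborOrders:
    """Neighbour orders (graph distances) from a source area.

    ``order[i]`` is the length of the shortest path from ``source`` to
    ``i``; ``order[source] = 0`` and first-order neighbours have order 1.
    Areas unreachable from the source carry ``numpy.inf``.
    """

    source: int
    order: np.ndarray

    @property
    def Mk(self) -> int:
        """Maximum finite order."""
        finite = self.order[np.isfinite(self.order)]
        return int(finite.max())

    @property
    def unreachable(self) -> np.ndarray:
        return np.flatnonzero(~np.isfinite(self.order))


def neighbor_orders(graph: AdjacencyGraph, k: int) -> NeighborOrders:
    """Breadth-first neighbour orders from area ``k`` (0-based)."""
    if not 0 <= k < graph.n:
        raise ValueError(f"source area {k} outside 0..{graph.n - 1}")
    dist = shortest_path(graph.W, method="D", unweighted=True, indices=k)
    if np.any(~np.isfinite(dist)):
        logger.warning(
            "graph is disconnected: %d area(s) unreachable from %d",
            int(np.sum(~np.isfinite(dist))), k,
        )
    return NeighborOrders(source=k, order=dist)


def structure_matrix(graph: AdjacencyGraph, c: float = 1.0) -> sp.csr_matrix:
    """Structure matrix ``Q(c) = D_w - c W`` (sparse).

    ``Q(1)`` is the graph Laplacian underlying the intrinsic CAR; its row
    sums vanish, so the all-ones vector spans its null space on a
    connected graph.
    """
    return (graph.Dw - c * graph.W).tocsr()
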