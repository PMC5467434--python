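"""Directed flag complexes and simplex censuses.

A directed n-simplex of a directed graph G is an ordered (n+1)-tuple
(v₀, …, vₙ) of distinct vertices with an edge vᵢ→vⱼ for every i < j.
The directed flag complex of G collects all such tuples, closed under
taking ordered subsets (faces).  Because tuples are ordered, two
simplices may share a vertex set: with reciprocal edges, (v₁,v₂,v₃) and
(v₂,v₁,v₃) are distinct 2-simplices.

Enumeration is by ordered sink extension: a k-simplex (v₀,…,vₖ) is
extended by every vertex u in the intersection of the out-neighborhoods
of all its vertices, producing each simplex exactly once.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .digraph import DirectedGraph, induced_subgraph
from .errors import ContractError, ResourceBudgetError, ValidationError

__all__ = [
    "SimplexTable",
    "ParticipationProfile",
    "build_flag_complex",
    "maximal_simplices",
    "participation",
    "subcomplex_census",
    "coskeleton",
    "closure",
]


@dataclass
class SimplexTable:
    """All directed simplices of a graph, grouped by dimension.

    ``simplices_by_dim[d]`` is an ``(n_d, d+1)`` integer array whose rows
    are the directed d-simplices in lexicographic order of their vertex
    tuples.  ``truncated`` records whether enumeration was stopped at a
    dimension cap, in which case maximality and Euler characteristics are
    undefined.
    """

    simplices_by_dim: list[np.ndarray]
    n_vertices: int
    truncated: bool = False

    @property
    def counts(self) -> list[int]:
        return [len(s) for s in self.simplices_by_dim]

    @property
    def max_dim(self) -> int:
        return len(self.simplices_by_dim) - 1

    def simplices(self, dim: int) -> np.ndarray:
        if dim < 0 or dim > self.max_dim:
            return np.empty((0, dim + 1), dtype=np.int64)
        return self.simplices_by_dim[dim]

    def as_tuple_sets(self) -> list[set[tuple[int, ...]]]:
        return [set(map(tuple, s)) for s in self.simplices_by_dim]

    def census_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dimension": range(self.max_dim + 1), "count": self.counts}
        )

    def write_census(self, path: str | Path) -> None:
        """Write the per-dimension census as CSV or JSON by extension."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(
                json.dumps({"counts": self.counts, "max_dim": self.max_dim})
            )
        else:
            self.census_frame().to_csv(path, index=False)


@dataclass
class ParticipationProfile:
    """Per-vertex and per-edge simplex participation counts.

    ``per_vertex_counts[v, d]`` is the number of d-simplices containing
    vertex v; column 0 is all ones.  ``per_edge_maximal_counts`` is a
    DataFrame indexed by ordered edge (pre, post) whose column ``d`` is
    the number of *maximal* d-simplices in which pre occurs before post.
    """

    per_vertex_counts: np.ndarray
    per_vertex_maxdim: np.ndarray
    per_edge_maximal_counts: pd.DataFrame


# ---------------------------------------------------------------------- #
# Enumeration
# ---------------------------------------------------------------------- #
def _iter_bits(mask: int):
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def build_flag_complex(
    g: DirectedGraph,
    max_dim: int | None = None,
    budget: int = 10_000_000,
) -> SimplexTable:
    """Enumerate the directed flag complex of ``g``.

    Parameters
    ----------
    max_dim
        Optional dimension cap; if given the resulting table is marked
        truncated (unless nothing was cut off).
    budget
        Abort with :class:`ResourceBudgetError` once the running simplex
        count exceeds this, naming the dimension reached.
    """
    out_masks = g.out_masks()
    dims: list[np.ndarray] = [np.arange(g.n_vertices, dtype=np.int64)[:, None]]
    total = g.n_vertices
    # frontier: (vertex tuple, bitmask of common out-neighbors)
    frontier: list[tuple[tuple[int, ...], int]] = [
        ((v,), out_masks[v]) for v in range(g.n_vertices)
    ]
    dim = 0
    while frontier and (max_dim is None or dim < max_dim):
        nxt: list[tuple[tuple[int, ...], int]] = []
        for verts, cand in frontier:
            for u in _iter_bits(cand):
                nxt.append((verts + (u,), cand & out_masks[u]))
        dim += 1
        total += len(nxt)
        if total > budget:
            raise ResourceBudgetError(
                f"simplex budget {budget} exceeded at dimension {dim}"
            )
        if nxt:
            dims.append(np.array([v for v, _ in nxt], dtype=np.int64))
        frontier = nxt
    truncated = max_dim is not None and bool(frontier) and any(
        c for _, c in frontier
    )
    return SimplexTable(dims, g.n_vertices, truncated=truncated)


def closure(
    simplices: Iterable[tuple[int, ...]], n_vertices: int
) -> SimplexTable:
    """Smallest simplicial complex containing the given ordered simplices:
    every ordered subset (face) of every input simplex."""
    by_dim: dict[int, set[tuple[int, ...]]] = {}
    for sigma in simplices:
        n = len(sigma)
        for size in range(1, n + 1):
            for combo in itertools.combinations(sigma, size):
                by_dim.setdefault(size - 1, set()).add(combo)
    top = max(by_dim) if by_dim else 0
    dims = []
    for d in range(top + 1):
        entries = sorted(by_dim.get(d, ()))
        dims.append(
            np.array(entries, dtype=np.int64).reshape(len(entries), d + 1)
        )
    return SimplexTable(dims, n_vertices)


def maximal_simplices(s: SimplexTable, g: DirectedGraph) -> SimplexTable:
    """Restrict a simplex table to its maximal simplices.

    A simplex (v₀,…,vₙ) is maximal iff no vertex u can be inserted at any
    position i — requiring edges vⱼ→u for j < i and u→vⱼ for j ≥ i — to
    form a directed (n+1)-simplex.  Insertion at arbitrary positions is
    required: extension at the sink alone would miss simplices that are
    faces of larger ones via internal insertion.
    """
    if s.truncated:
        raise ContractError("maximality is undecidable on a truncated table")
    out_masks = g.out_masks()
    in_masks = g.in_masks()
    dims: list[np.ndarray] = []
    for d in range(s.max_dim + 1):
        keep = []
        for row in s.simplices_by_dim[d]:
            verts = [int(v) for v in row]
            k = len(verts)
            # prefix[i] = AND of out-neighborhoods of verts[:i]
            full = (1 << g.n_vertices) - 1
            prefix = [full]
            for v in verts:
                prefix.append(prefix[-1] & out_masks[v])
            suffix = [full]
            for v in reversed(verts):
                suffix.append(suffix[-1] & in_masks[v])
            suffix.reverse()  # suffix[i] = AND of in-neighborhoods of verts[i:]
            maximal = True
            for i in range(k + 1):
                if prefix[i] & suffix[i]:
                    maximal = False
                    break
            if maximal:
                keep.append(row)
        dims.append(
            np.array(keep, dtype=np.int64).reshape(len(keep), d + 1)
        )
    while len(dims) > 1 and len(dims[-1]) == 0:
        dims.pop()
    return SimplexTable(dims, s.n_vertices)


# ---------------------------------------------------------------------- #
# Censuses
# ---------------------------------------------------------------------- #
def participation(
    s: SimplexTable,
    g: DirectedGraph,
    maximal: SimplexTable | None = None,
) -> ParticipationProfile:
    """Per-vertex simplex membership and per-edge maximal-simplex counts.

    An edge that lies in no maximal simplex of dimension ≥ 2 is itself a
    maximal 1-simplex and appears with count 1 in column 1.
    """
    if maximal is None:
        maximal = maximal_simplices(s, g)
    n_dims = s.max_dim + 1
    per_vertex = np.zeros((g.n_vertices, n_dims), dtype=np.int64)
    for d in range(n_dims):
        simp = s.simplices_by_dim[d]
        if len(simp):
            np.add.at(per_vertex[:, d], simp.ravel(), 1)
    maxdim = np.zeros(g.n_vertices, dtype=np.int64)
    for d in range(n_dims):
        maxdim[per_vertex[:, d] > 0] = d

    edge_index = {tuple(e): i for i, e in enumerate(map(tuple, g.edges))}
    per_edge = np.zeros((g.n_edges, n_dims), dtype=np.int64)
    for d in range(1, maximal.max_dim + 1):
        for row in maximal.simplices_by_dim[d]:
            verts = [int(v) for v in row]
            for i, j in itertools.combinations(range(len(verts)), 2):
                per_edge[edge_index[(verts[i], verts[j])], d] += 1
    frame = pd.DataFrame(
        per_edge,
        index=pd.MultiIndex.from_arrays(
            [g.edges[:, 0], g.edges[:, 1]], names=["pre", "post"]
        ),
        columns=range(n_dims),
    )
    return ParticipationProfile(per_vertex, maxdim, frame)


def subcomplex_census(
    g: DirectedGraph,
    vertex_filter: Callable[[pd.Series], bool],
    max_dim: int | None = None,
) -> SimplexTable:
    """Flag complex of the induced subgraph on vertices passing a label
    predicate (e.g. excitatory-only, or a single layer).

    An empty selection yields an empty table, not an error.
    """
    if g.vertex_labels is None:
        raise ValidationError("subcomplex_census requires vertex_labels")
    sub, _ = induced_subgraph(g, vertex_filter)
    return build_flag_complex(sub, max_dim=max_dim)


def coskeleton(s: SimplexTable, k: int) -> SimplexTable:
    """The k-coskeleton: all simplices of dimension ≥ k together with all
    of their faces.  For k = 0 this is the whole complex."""
    if k > s.max_dim:
        raise ValueError(f"k={k} exceeds max_dim={s.max_dim}")
    if k <= 0:
        return s
    top = [tuple(map(int, row)) for d in range(k, s.max_dim + 1)
           for row in s.simplices_by_dim[d]]
    return closure(top, s.n_vertices)
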