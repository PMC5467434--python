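"""Directed-graph data model, I/O, and elementary directionality statistics.

The central object is :class:`DirectedGraph`: a simple directed graph
(no self-loops, at most one edge per ordered pair, reciprocal pairs
allowed) with optional 3-D soma positions (μm) and per-vertex categorical
labels (layer, morphological type, excitatory/inhibitory class).

Conventions
-----------
* Vertex ids are 0-based and dense.  Readers re-index sparse id spaces
  and keep the original ids in ``vertex_ids``.
* In adjacency-matrix form, rows are presynaptic (edge source) and
  columns postsynaptic (edge target).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite
from scipy.sparse import csgraph

from .errors import ResourceBudgetError, ValidationError

__all__ = [
    "DirectedGraph",
    "MotifCensus",
    "read_graph",
    "write_graph",
    "signed_degree",
    "directionality",
    "is_acyclic",
    "motif_census",
    "weakly_connected_components",
    "induced_subgraph",
]


@dataclass
class DirectedGraph:
    """A finite simple directed graph with optional neuron metadata.

    Parameters
    ----------
    n_vertices
        Number of vertices; ids are ``0 .. n_vertices-1``.
    edges
        ``(m, 2)`` integer array of ordered (source, target) pairs,
        lexicographically sorted and duplicate-free.
    positions
        Optional ``(n_vertices, 3)`` float array of soma positions in μm.
    vertex_labels
        Optional DataFrame with one row per vertex (e.g. columns
        ``layer``, ``mtype``, ``synapse_class``).
    vertex_ids
        Original vertex identifiers when the input id space was sparse.
    """

    n_vertices: int
    edges: np.ndarray
    positions: np.ndarray | None = None
    vertex_labels: pd.DataFrame | None = None
    vertex_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            order = np.lexsort((self.edges[:, 1], self.edges[:, 0]))
            self.edges = self.edges[order]
        self._validate()

    # ------------------------------------------------------------------ #
    @classmethod
    def from_edges(
        cls,
        n_vertices: int,
        edges: Iterable[tuple[int, int]],
        positions: np.ndarray | None = None,
        vertex_labels: pd.DataFrame | None = None,
    ) -> "DirectedGraph":
        arr = np.array(sorted(set((int(u), int(v)) for u, v in edges)), dtype=np.int64)
        if arr.size == 0:
            arr = np.empty((0, 2), dtype=np.int64)
        return cls(n_vertices, arr, positions=positions, vertex_labels=vertex_labels)

    def _validate(self) -> None:
        e = self.edges
        if e.size:
            if e.min() < 0 or e.max() >= self.n_vertices:
                raise ValidationError(
                    f"edge endpoint out of range [0, {self.n_vertices})"
                )
            loops = np.nonzero(e[:, 0] == e[:, 1])[0]
            if loops.size:
                raise ValidationError(f"self-loop at vertex {e[loops[0], 0]}")
            if len(e) > 1 and np.any(np.all(np.diff(e, axis=0) == 0, axis=1)):
                dup = np.nonzero(np.all(np.diff(e, axis=0) == 0, axis=1))[0][0]
                raise ValidationError(f"duplicate edge {tuple(e[dup])}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.n_vertices, 3):
                raise ValidationError("positions must have shape (n_vertices, 3)")
        if self.vertex_labels is not None and len(self.vertex_labels) != self.n_vertices:
            raise ValidationError("vertex_labels must have one row per vertex")

    # ------------------------------------------------------------------ #
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(map(tuple, self.edges))

    def has_edge(self, u: int, v: int) -> bool:
        return (u, v) in self.edge_set()

    def adjacency(self) -> sparse.csr_matrix:
        """Boolean adjacency matrix; row = presynaptic, column = postsynaptic."""
        data = np.ones(self.n_edges, dtype=bool)
        return sparse.csr_matrix(
            (data, (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n_vertices, self.n_vertices),
        )

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 1], minlength=self.n_vertices)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 0], minlength=self.n_vertices)

    def out_masks(self) -> list[int]:
        """Out-neighborhoods as bitmasks (bit v set ⇔ edge u→v exists)."""
        masks = [0] * self.n_vertices
        for u, v in self.edges:
            masks[u] |= 1 << int(v)
        return masks

    def in_masks(self) -> list[int]:
        masks = [0] * self.n_vertices
        for u, v in self.edges:
            masks[v] |= 1 << int(u)
        return masks

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(map(tuple, self.edges))
        return g


@dataclass(frozen=True)
class MotifCensus:
    """Counts of fully connected directed configurations on k labeled vertices."""

    k: int
    n_total_configurations: int
    n_unidirectional: int
    n_acyclic: int
    n_cyclic: int

    def as_dict(self) -> dict[str, int]:
        return {
            "k": self.k,
            "n_total_configurations": self.n_total_configurations,
            "n_unidirectional": self.n_unidirectional,
            "n_acyclic": self.n_acyclic,
            "n_cyclic": self.n_cyclic,
        }


# ---------------------------------------------------------------------- #
# I/O
# ---------------------------------------------------------------------- #
def _infer_format(path: Path) -> str:
    if path.suffix.lower() in {".mtx", ".mm"}:
        return "matrix-market"
    return "edge-list-csv"


def read_graph(path: str | Path, format: str | None = None) -> DirectedGraph:
    """Read a directed graph from an edge-list CSV or a Matrix Market file.

    CSV: two integer columns ``pre,post`` (header optional), 0-based ids.
    Matrix Market: coordinate format, 1-based per the standard, rows
    presynaptic; converted to 0-based internally.

    Sparse id spaces are re-indexed densely; the original ids are kept in
    ``vertex_ids``.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "matrix-market":
        mat = mmread(str(path)).tocoo()
        if mat.shape[0] != mat.shape[1]:
            raise ValidationError(f"{path}: adjacency matrix must be square")
        pre, post = mat.row, mat.col
        if np.any(pre == post):
            v = pre[np.nonzero(pre == post)[0][0]]
            raise ValidationError(f"{path}: self-loop at vertex {v} (1-based {v + 1})")
        pairs = list(zip(pre.tolist(), post.tolist()))
        if len(set(pairs)) != len(pairs):
            raise ValidationError(f"{path}: duplicate entries in coordinate listing")
        return DirectedGraph.from_edges(mat.shape[0], pairs)
    if fmt == "edge-list-csv":
        rows: list[tuple[int, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = [p.strip() for p in line.split(",")[:2]]
                if lineno == 1 and not all(_is_int(p) for p in parts):
                    continue  # header row
                if not all(_is_int(p) for p in parts) or len(parts) != 2:
                    raise ValidationError(
                        f"{path}:{lineno}: expected two integer columns, got {line!r}"
                    )
                u, v = int(parts[0]), int(parts[1])
                if u == v:
                    raise ValidationError(f"{path}:{lineno}: self-loop {u}->{v}")
                if (u, v) in set(rows):
                    raise ValidationError(f"{path}:{lineno}: duplicate edge {u}->{v}")
                rows.append((u, v))
        ids = sorted({u for u, _ in rows} | {v for _, v in rows})
        dense = {orig: i for i, orig in enumerate(ids)}
        g = DirectedGraph.from_edges(len(ids), [(dense[u], dense[v]) for u, v in rows])
        g.vertex_ids = np.array(ids, dtype=np.int64)
        return g
    raise ValueError(f"unknown graph format {fmt!r}")


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def write_graph(g: DirectedGraph, path: str | Path, format: str | None = None) -> None:
    """Write a graph as edge-list CSV or Matrix Market coordinate file."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "matrix-market":
        coo = sparse.coo_matrix(
            (np.ones(g.n_edges, dtype=np.int8), (g.edges[:, 0], g.edges[:, 1])),
            shape=(g.n_vertices, g.n_vertices),
        )
        mmwrite(str(path), coo, field="integer")
    elif fmt == "edge-list-csv":
        with open(path, "w") as fh:
            fh.write("pre,post\n")
            for u, v in g.edges:
                fh.write(f"{u},{v}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


# ---------------------------------------------------------------------- #
# Degree statistics and directionality
# ---------------------------------------------------------------------- #
def signed_degree(g: DirectedGraph, v: int) -> int:
    """In-degree minus out-degree of vertex ``v``.

    Summed over all vertices of any graph, signed degrees cancel to zero;
    the square-sum of signed degrees defines the graph's directionality.
    """
    if not 0 <= v < g.n_vertices:
        raise IndexError(f"vertex {v} out of range [0, {g.n_vertices})")
    return int(g.in_degrees()[v]) - int(g.out_degrees()[v])


def signed_degrees(g: DirectedGraph) -> np.ndarray:
    return g.in_degrees().astype(np.int64) - g.out_degrees().astype(np.int64)


def directionality(g: DirectedGraph) -> int:
    """Net directionality Dr(G) = Σ_v (indeg(v) − outdeg(v))².

    Among fully connected unidirectional graphs on n+1 vertices this is
    maximized exactly by the acyclic ones (directed n-simplices), for
    which it equals n(n+1)(n+2)/3.
    """
    sd = signed_degrees(g)
    return int(np.sum(sd * sd))


def is_acyclic(g: DirectedGraph) -> bool:
    """True iff the graph contains no oriented cycle.

    A reciprocal pair u→v, v→u is an oriented cycle of length 2, so a
    graph with any reciprocal connection is not acyclic.
    """
    return nx.is_directed_acyclic_graph(g.to_networkx())


def weakly_connected_components(g: DirectedGraph) -> list[np.ndarray]:
    """Partition of the vertex set into components of the underlying
    undirected graph, each a sorted array of vertex ids."""
    n_comp, labels = csgraph.connected_components(
        g.adjacency(), directed=True, connection="weak"
    )
    return [np.nonzero(labels == c)[0] for c in range(n_comp)]


def induced_subgraph(
    g: DirectedGraph, keep: np.ndarray | Sequence[int] | Callable[[pd.Series], bool]
) -> tuple[DirectedGraph, np.ndarray]:
    """Induced subgraph on a vertex subset.

    ``keep`` is a boolean mask, a list of vertex ids, or a predicate
    applied to rows of ``vertex_labels``.  Returns the re-indexed
    subgraph and the array of original vertex ids.
    """
    if callable(keep):
        if g.vertex_labels is None:
            raise ValidationError("vertex predicate requires vertex_labels")
        mask = g.vertex_labels.apply(keep, axis=1).to_numpy(dtype=bool)
    else:
        keep = np.asarray(keep)
        if keep.dtype == bool:
            mask = keep
        else:
            mask = np.zeros(g.n_vertices, dtype=bool)
            mask[keep] = True
    ids = np.nonzero(mask)[0]
    remap = -np.ones(g.n_vertices, dtype=np.int64)
    remap[ids] = np.arange(len(ids))
    if g.n_edges:
        sel = mask[g.edges[:, 0]] & mask[g.edges[:, 1]]
        new_edges = remap[g.edges[sel]]
    else:
        new_edges = np.empty((0, 2), dtype=np.int64)
    sub = DirectedGraph(
        len(ids),
        new_edges,
        positions=g.positions[ids] if g.positions is not None else None,
        vertex_labels=(
            g.vertex_labels.iloc[ids].reset_index(drop=True)
            if g.vertex_labels is not None
            else None
        ),
    )
    return sub, ids


# ---------------------------------------------------------------------- #
# Motif census
# ---------------------------------------------------------------------- #
def _tuple_graph_acyclic(k: int, edges: list[tuple[int, int]]) -> bool:
    # Iterative DFS cycle check on <= 5 vertices.
    adj = [[] for _ in range(k)]
    for u, v in edges:
        adj[u].append(v)
    color = [0] * k  # 0 white, 1 gray, 2 black
    for start in range(k):
        if color[start]:
            continue
        stack = [(start, iter(adj[start]))]
        color[start] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == 1:
                    return False
                if color[nxt] == 0:
                    color[nxt] = 1
                    stack.append((nxt, iter(adj[nxt])))
                    advanced = True
                    break
            if not advanced:
                color[node] = 2
                stack.pop()
    return True


def motif_census(k: int) -> MotifCensus:
    """Exhaustive census of fully connected directed configurations on
    ``k`` labeled vertices.

    Each of the k(k−1)/2 unordered pairs is assigned one of three states
    (u→v, v→u, or reciprocal u↔v), giving 3^(k(k−1)/2) configurations.
    Unidirectional configurations (no reciprocal pair) split into acyclic
    ones — the directed (k−1)-simplices — and ones containing an oriented
    cycle.  Counting is on labeled vertices, without any isomorphism
    quotient.
    """
    if k < 2:
        raise ValueError("motif census requires k >= 2")
    if k > 5:
        raise ResourceBudgetError(
            f"motif census on k={k} would enumerate 3^{k * (k - 1) // 2} states"
        )
    pairs = list(itertools.combinations(range(k), 2))
    n_pairs = len(pairs)
    n_total = 3**n_pairs
    n_unidir = 0
    n_acyclic = 0
    for states in itertools.product(range(3), repeat=n_pairs):
        if 2 in states:
            continue  # reciprocal pair present: not unidirectional
        n_unidir += 1
        edges = [
            (u, v) if s == 0 else (v, u) for (u, v), s in zip(pairs, states)
        ]
        if _tuple_graph_acyclic(k, edges):
            n_acyclic += 1
    return MotifCensus(
        k=k,
        n_total_configurations=n_total,
        n_unidirectional=n_unidir,
        n_acyclic=n_acyclic,
        n_cyclic=n_unidir - n_acyclic,
    )
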