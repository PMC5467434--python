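"""Density-matched control connectivity models.

Three controls matched to a reference connectome, each preserving the
vertex set and the total number of connections:

* **ER** — directed Erdős–Rényi analog: the same number of edges drawn
  uniformly from all ordered off-diagonal pairs; removes all biological
  structure.
* **PR** — "Peters' rule" pruning: a uniform subset of a permissive
  candidate graph (e.g. axo-dendritic appositions, or any structural
  prior) cut down to the reference edge count; keeps only what the
  candidate geometry implies.
* **GB** — general-biology shuffle: connections are regrouped by
  (pre-type, post-type) and by binned soma distance, and each
  connection's postsynaptic target is resampled within its bin;
  preserves cell-type wiring rates and the distance profile of
  connected pairs while erasing pairwise specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .digraph import DirectedGraph
from .errors import ContractError, ValidationError

__all__ = ["er_control", "pr_control", "gb_control", "NullModelSpec"]

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE_BIN_UM = 75.0


@dataclass(frozen=True)
class NullModelSpec:
    """Declarative description of one control model run."""

    kind: str  # {"ER", "PR", "GB"}
    seed: int
    distance_bin: float = DEFAULT_DISTANCE_BIN_UM
    candidate_graph: DirectedGraph | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"ER", "PR", "GB"}:
            raise ValueError(f"unknown null-model kind {self.kind!r}")
        if self.distance_bin <= 0:
            raise ValueError("distance_bin must be positive")


def _carry_metadata(ref: DirectedGraph, edges: np.ndarray) -> DirectedGraph:
    return DirectedGraph(
        ref.n_vertices,
        edges,
        positions=ref.positions,
        vertex_labels=ref.vertex_labels,
    )


def er_control(reference: DirectedGraph, seed: int) -> DirectedGraph:
    """Uniform random directed graph with the reference's exact vertex and
    edge counts (no self-loops, no duplicate ordered pairs)."""
    n, m = reference.n_vertices, reference.n_edges
    if n < 2:
        raise ValidationError("ER control requires at least 2 vertices")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n * (n - 1), size=m, replace=False)
    pre, r = idx // (n - 1), idx % (n - 1)
    post = r + (r >= pre)  # skip the diagonal
    return _carry_metadata(reference, np.column_stack([pre, post]))


def pr_control(
    candidate: DirectedGraph, target_edge_count: int, seed: int
) -> DirectedGraph:
    """Uniformly chosen subset of the candidate graph's edges of exactly
    ``target_edge_count`` edges (pruning a permissive structural prior
    down to the reference density)."""
    if target_edge_count > candidate.n_edges:
        raise ContractError(
            f"target {target_edge_count} exceeds candidate size {candidate.n_edges}"
        )
    rng = np.random.default_rng(seed)
    keep = rng.choice(candidate.n_edges, size=target_edge_count, replace=False)
    return _carry_metadata(candidate, candidate.edges[np.sort(keep)])


def _labels_array(
    g: DirectedGraph, type_of: Callable[[int], object] | Sequence | str | None
) -> np.ndarray:
    if callable(type_of):
        return np.array([type_of(v) for v in range(g.n_vertices)])
    if isinstance(type_of, str):
        if g.vertex_labels is None or type_of not in g.vertex_labels:
            raise ValidationError(f"vertex label column {type_of!r} not present")
        return g.vertex_labels[type_of].to_numpy()
    if type_of is not None:
        arr = np.asarray(type_of)
        if len(arr) != g.n_vertices:
            raise ValidationError("type array must have one entry per vertex")
        return arr
    if g.vertex_labels is not None:
        for col in ("mtype", "synapse_class", "layer"):
            if col in g.vertex_labels:
                return g.vertex_labels[col].to_numpy()
    return np.zeros(g.n_vertices, dtype=np.int64)


def gb_control(
    reference: DirectedGraph,
    type_of: Callable[[int], object] | Sequence | str | None = None,
    seed: int = 0,
    distance_bin: float = DEFAULT_DISTANCE_BIN_UM,
    max_retries: int = 100,
) -> DirectedGraph:
    """Distance-preserving shuffle of the reference connectivity.

    Edges are partitioned by (pre-type, post-type); within each block
    the postsynaptic target of every connection is resampled uniformly
    among vertices of the same post-type whose Euclidean soma distance
    from the source falls in the same ``distance_bin``-wide bin (bin
    edges at multiples of ``distance_bin`` from 0).  Per-block edge
    counts and the binned soma-distance histogram of connected pairs are
    preserved exactly.

    Resampling may return the original target.  A draw producing a
    self-loop or a duplicate ordered pair is retried up to
    ``max_retries`` times, after which the original target is kept (and
    the event logged); a bin with no alternative target likewise keeps
    the original.
    """
    if reference.positions is None:
        raise ValidationError("GB control requires vertex positions")
    if distance_bin <= 0:
        raise ValueError("distance_bin must be positive")
    labels = _labels_array(reference, type_of)
    pos = reference.positions
    rng = np.random.default_rng(seed)

    pre = reference.edges[:, 0]
    post = reference.edges[:, 1]
    dists = np.linalg.norm(pos[pre] - pos[post], axis=1)
    bins = np.floor(dists / distance_bin).astype(np.int64)

    by_label: dict[object, np.ndarray] = {
        lab: np.nonzero(labels == lab)[0] for lab in np.unique(labels)
    }
    chosen: set[tuple[int, int]] = set()
    new_edges = np.empty_like(reference.edges)
    # Deterministic order: edges are stored lexicographically sorted.
    for k in range(len(pre)):
        u, v_orig, b = int(pre[k]), int(post[k]), int(bins[k])
        pool = by_label[labels[v_orig]]
        d_pool = np.linalg.norm(pos[pool] - pos[u], axis=1)
        cand = pool[np.floor(d_pool / distance_bin).astype(np.int64) == b]
        cand = cand[cand != u]
        v_new = v_orig
        if len(cand) <= 1:
            logger.debug("edge (%d,%d): no alternative target in bin %d", u, v_orig, b)
        else:
            for _ in range(max_retries):
                draw = int(cand[rng.integers(len(cand))])
                if (u, draw) not in chosen:
                    v_new = draw
                    break
            else:
                logger.debug(
                    "edge (%d,%d): duplicate collisions, keeping original", u, v_orig
                )
        if (u, v_new) in chosen:
            # Original also collides (it was resampled into earlier);
            # fall back to any free candidate in the bin.
            free = [int(c) for c in cand if (u, int(c)) not in chosen]
            if not free:
                raise ContractError(
                    f"cannot place edge ({u},{v_orig}) without duplication"
                )
            v_new = free[int(rng.integers(len(free)))]
        chosen.add((u, v_new))
        new_edges[k] = (u, v_new)
    return _carry_metadata(reference, new_edges)


def soma_distance_histogram(
    g: DirectedGraph,
    type_of: Callable[[int], object] | Sequence | str | None = None,
    distance_bin: float = DEFAULT_DISTANCE_BIN_UM,
) -> pd.DataFrame:
    """Per-(pre-type, post-type) histogram of binned soma distances of
    connected pairs — the statistic the GB shuffle preserves exactly."""
    if g.positions is None:
        raise ValidationError("soma distance histogram requires positions")
    labels = _labels_array(g, type_of)
    pre, post = g.edges[:, 0], g.edges[:, 1]
    d = np.linalg.norm(g.positions[pre] - g.positions[post], axis=1)
    frame = pd.DataFrame(
        {
            "pre_type": labels[pre],
            "post_type": labels[post],
            "distance_bin": np.floor(d / distance_bin).astype(np.int64),
        }
    )
    return (
        frame.value_counts(["pre_type", "post_type", "distance_bin"])
        .rename("count")
        .reset_index()
        .sort_values(["pre_type", "post_type", "distance_bin"])
        .reset_index(drop=True)
    )
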