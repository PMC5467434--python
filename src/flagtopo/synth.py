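"""Synthetic circuits, reference complexes, and correlated spike trains.

These generators stand in for a full anatomical reconstruction and its
biophysical simulation: they produce layered geometric circuits with
distance-dependent connectivity, small complexes with analytically known
homology, spike trains whose correlation structure is concentrated on
chosen neuron ensembles (typically directed simplices of a target
graph), and the in-silico "patch-clamp" sampling census.

The spike generator injects, for each ensemble, a Poisson stream of
coactivation events; each event triggers one spike per participating
member with an ordered cumulative delay (source earliest, sink latest)
plus independent jitter, on top of independent Poisson background.  Two
dials create the statistical structure the structure-function analyses
probe: coactivation rates that grow with ensemble dimension (pairs
inside larger cliques share more events), and per-member participation
probabilities that ramp up toward the sink (sink-adjacent pairs share
the most drive).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .activity import SpikeTrainSet
from .digraph import DirectedGraph, induced_subgraph
from .errors import ValidationError
from .flag import SimplexTable, build_flag_complex

__all__ = [
    "CircuitSpec",
    "SpikeGenSpec",
    "Ensemble",
    "exponential_kernel",
    "make_circuit",
    "known_complex",
    "disjoint_union",
    "make_spikes",
    "ensembles_from_simplices",
    "sample_patch",
]


# ---------------------------------------------------------------------- #
# Geometric circuits
# ---------------------------------------------------------------------- #
def exponential_kernel(
    p_max: float = 0.15, scale_um: float = 150.0
) -> Callable[[np.ndarray, pd.DataFrame, pd.DataFrame], np.ndarray]:
    """Distance-decaying connection kernel p(d) = p_max · exp(−d/scale)."""

    def kernel(dist, pre_labels, post_labels):
        return p_max * np.exp(-dist / scale_um)

    return kernel


@dataclass
class CircuitSpec:
    """Layered slab circuit with distance-dependent connectivity.

    Layers are stacked slabs in depth (z, μm); somata are uniform in
    each slab and over a square lateral extent.  Each ordered pair is
    connected independently with probability given by the kernel, a
    function of soma distance and the pre/post label rows.  Defaults
    give a two-layer, 200-neuron circuit dense enough to contain
    directed simplices up to dimension ~4 while staying desk-scale.
    """

    layer_counts: Sequence[int] = (100, 100)
    layer_boundaries: Sequence[float] = (0.0, 200.0, 400.0)
    lateral_extent: float = 300.0
    kernel: Callable | None = None
    excitatory_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_boundaries) != len(self.layer_counts) + 1:
            raise ValidationError("need one more boundary than layer counts")
        if np.any(np.diff(self.layer_boundaries) <= 0):
            raise ValidationError("layer boundaries must be strictly increasing")
        if not 0 <= self.excitatory_fraction <= 1:
            raise ValidationError("excitatory_fraction must lie in [0, 1]")


def make_circuit(spec: CircuitSpec) -> DirectedGraph:
    """Sample a circuit: positions per layer slab, labels, and edges
    drawn independently per ordered pair from the kernel probability."""
    rng = np.random.default_rng(spec.seed)
    kernel = spec.kernel or exponential_kernel()
    n = int(sum(spec.layer_counts))
    pos = np.empty((n, 3))
    layer = np.empty(n, dtype=np.int64)
    start = 0
    for li, cnt in enumerate(spec.layer_counts):
        z0, z1 = spec.layer_boundaries[li], spec.layer_boundaries[li + 1]
        pos[start:start + cnt, 0] = rng.uniform(0, spec.lateral_extent, cnt)
        pos[start:start + cnt, 1] = rng.uniform(0, spec.lateral_extent, cnt)
        pos[start:start + cnt, 2] = rng.uniform(z0, z1, cnt)
        layer[start:start + cnt] = li + 1
        start += cnt
    exc = rng.random(n) < spec.excitatory_fraction
    labels = pd.DataFrame(
        {
            "layer": layer,
            "synapse_class": np.where(exc, "EXC", "INH"),
        }
    )
    labels["mtype"] = "L" + labels["layer"].astype(str) + "_" + labels["synapse_class"]
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    prob = np.asarray(kernel(dist, labels, labels), dtype=float)
    np.fill_diagonal(prob, 0.0)
    draw = rng.random((n, n)) < prob
    pre, post = np.nonzero(draw)
    return DirectedGraph(
        n, np.column_stack([pre, post]), positions=pos, vertex_labels=labels
    )


# ---------------------------------------------------------------------- #
# Reference complexes of known homology
# ---------------------------------------------------------------------- #
def _simplex_graph(n: int) -> DirectedGraph:
    edges = [(i, j) for i in range(n + 1) for j in range(i + 1, n + 1)]
    return DirectedGraph.from_edges(n + 1, edges)


def _octahedron_sphere() -> DirectedGraph:
    # Octahedron on 6 vertices, antipodal pairs (0,5), (1,4), (2,3) not
    # adjacent; every other pair connected low index -> high index.
    # The directed flag complex is eight triangles tiling a 2-sphere:
    # Betti profile (1, 0, 1).
    antipodal = {(0, 5), (1, 4), (2, 3)}
    edges = [
        (i, j)
        for i in range(6)
        for j in range(i + 1, 6)
        if (i, j) not in antipodal
    ]
    return DirectedGraph.from_edges(6, edges)


def disjoint_union(*graphs: DirectedGraph) -> DirectedGraph:
    """Disjoint union with vertex ids shifted block-wise."""
    offset = 0
    edges: list[tuple[int, int]] = []
    for g in graphs:
        edges.extend((int(u) + offset, int(v) + offset) for u, v in g.edges)
        offset += g.n_vertices
    return DirectedGraph.from_edges(offset, edges)


def known_complex(name: str) -> DirectedGraph:
    """Named reference graphs with analytically known flag-complex homology.

    ``simplex-n``: acyclic tournament on n+1 vertices (Betti (1, 0, …));
    ``cycle-3``: directed 3-cycle (Betti (1, 1): a circle — it carries
    three 1-simplices and no 2-simplex);
    ``octahedron-sphere``: eight directed triangles tiling a 2-sphere
    (Betti (1, 0, 1));
    ``disjoint-union(a,b,…)``: disjoint union of other named complexes.
    """
    name = name.strip()
    m = re.fullmatch(r"simplex-(\d+)", name)
    if m:
        return _simplex_graph(int(m.group(1)))
    if name == "cycle-3":
        return DirectedGraph.from_edges(3, [(0, 1), (1, 2), (2, 0)])
    if name == "octahedron-sphere":
        return _octahedron_sphere()
    m = re.fullmatch(r"disjoint-union\((.*)\)", name)
    if m:
        parts = [p for p in m.group(1).split(",") if p.strip()]
        return disjoint_union(*(known_complex(p) for p in parts))
    raise ValueError(f"unknown complex name {name!r}")


# ---------------------------------------------------------------------- #
# Correlated spike trains
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class Ensemble:
    """A coactivating neuron ensemble (typically a directed simplex).

    ``rate`` is the coactivation-event rate in Hz; ``jitter`` (ms) sets
    both the per-position transmission lag and the independent spike
    jitter; ``participation`` gives each member's probability of firing
    on a given event, either one value per member or a (source, sink)
    ramp interpolated linearly along the ensemble order.
    """

    members: tuple[int, ...]
    rate: float
    jitter: float = 2.0
    participation: tuple[float, ...] = (1.0, 1.0)

    def member_probabilities(self) -> np.ndarray:
        k = len(self.members)
        p = np.asarray(self.participation, dtype=float)
        if p.size == k:
            return p
        if p.size == 2:
            return np.linspace(p[0], p[1], k)
        raise ValidationError("participation must have 2 or len(members) entries")


@dataclass
class SpikeGenSpec:
    """Spike generator: Poisson background plus ensemble coactivation."""

    n_neurons: int
    duration: float = 5000.0  # ms
    n_trials: int = 30
    baseline_rate: float = 1.0  # Hz
    ensembles: Sequence[Ensemble] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValidationError("baseline rate must be non-negative")
        for ens in self.ensembles:
            if ens.rate < 0 or ens.jitter < 0:
                raise ValidationError("ensemble rates and jitter must be non-negative")


def ensembles_from_simplices(
    table: SimplexTable,
    rate_per_dim: float = 0.5,
    jitter: float = 2.0,
    participation: tuple[float, float] = (0.6, 1.0),
    min_dim: int = 1,
) -> list[Ensemble]:
    """Ensembles from the simplices of a table, one per simplex of
    dimension ≥ ``min_dim``, with coactivation rate ``rate_per_dim · dim``
    so that pairs inside higher-dimensional cliques share more events."""
    out = []
    for d in range(min_dim, table.max_dim + 1):
        for row in table.simplices(d):
            out.append(
                Ensemble(
                    tuple(int(v) for v in row),
                    rate=rate_per_dim * d,
                    jitter=jitter,
                    participation=participation,
                )
            )
    return out


def make_spikes(
    spec: SpikeGenSpec, structure: DirectedGraph | None = None
) -> SpikeTrainSet:
    """Generate spike trains: homogeneous Poisson background per neuron,
    plus ensemble coactivation events with ordered per-member delays
    (member at position m spikes ~m·jitter after the event, uniformly
    jittered), independent across trials and deterministic under seed.
    """
    if structure is not None and structure.n_vertices != spec.n_neurons:
        raise ValidationError("structure size must match n_neurons")
    rng = np.random.default_rng(spec.seed)
    T = spec.duration
    spikes: list[list[np.ndarray]] = [[] for _ in range(spec.n_neurons)]
    for _trial in range(spec.n_trials):
        per_neuron: list[list[np.ndarray]] = [[] for _ in range(spec.n_neurons)]
        lam = spec.baseline_rate * T / 1000.0
        for j in range(spec.n_neurons):
            cnt = rng.poisson(lam)
            per_neuron[j].append(rng.uniform(0, T, cnt))
        for ens in spec.ensembles:
            n_events = rng.poisson(ens.rate * T / 1000.0)
            if n_events == 0:
                continue
            events = rng.uniform(0, T, n_events)
            probs = ens.member_probabilities()
            for m, v in enumerate(ens.members):
                fire = rng.random(n_events) < probs[m]
                if not fire.any():
                    continue
                times = (
                    events[fire]
                    + m * ens.jitter
                    + rng.uniform(0, ens.jitter, int(fire.sum()))
                )
                per_neuron[v].append(times)
        for j in range(spec.n_neurons):
            merged = np.concatenate(per_neuron[j]) if per_neuron[j] else np.empty(0)
            merged = np.unique(merged)
            spikes[j].append(merged[(merged >= 0) & (merged < T)])
    return SpikeTrainSet(spikes, duration=T)


# ---------------------------------------------------------------------- #
# In-silico patch sampling
# ---------------------------------------------------------------------- #
def sample_patch(
    g: DirectedGraph,
    box: tuple[float, float, float] = (200.0, 200.0, 20.0),
    max_cells: int = 12,
    keep_fraction: float = 0.5,
    n_experiments: int = 100,
    seed: int = 0,
    label_filter: Callable[[pd.Series], bool] | None = None,
) -> pd.DataFrame:
    """Simulated multi-neuron patch sampling census.

    Per experiment: place a box of the given dimensions uniformly inside
    the circuit's bounding volume, take the vertices inside it (after an
    optional label filter, e.g. a target morphological type), randomly
    discard each with probability 1 − ``keep_fraction``, cap the
    survivors at ``max_cells`` (uniform subset), and count the directed
    simplices of the induced subgraph per dimension.

    Returns a tidy frame (experiment, dimension, count); aggregate with
    ``df.groupby("dimension")["count"].sum()``.
    """
    if g.positions is None:
        raise ValidationError("sample_patch requires positions")
    rng = np.random.default_rng(seed)
    pos = g.positions
    if label_filter is not None:
        if g.vertex_labels is None:
            raise ValidationError("label_filter requires vertex_labels")
        eligible = g.vertex_labels.apply(label_filter, axis=1).to_numpy(dtype=bool)
    else:
        eligible = np.ones(g.n_vertices, dtype=bool)
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    span = np.maximum(hi - lo - np.asarray(box), 0.0)
    rows = []
    for exp in range(n_experiments):
        origin = lo + rng.uniform(0, 1, 3) * span
        inside = np.all((pos >= origin) & (pos <= origin + np.asarray(box)), axis=1)
        ids = np.nonzero(inside & eligible)[0]
        ids = ids[rng.random(len(ids)) < keep_fraction]
        if len(ids) > max_cells:
            ids = rng.choice(ids, size=max_cells, replace=False)
        sub, _ = induced_subgraph(g, np.sort(ids))
        counts = build_flag_complex(sub).counts if sub.n_vertices else [0]
        for d, cnt in enumerate(counts):
            rows.append({"experiment": exp, "dimension": d, "count": cnt})
    return pd.DataFrame(rows, columns=["experiment", "dimension", "count"])
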