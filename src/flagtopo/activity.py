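"""Structure-function layer: spike trains, PSTHs, correlation matrices,
transmission-response graph series, and the analyses relating spike
correlations to simplex membership.

The transmission-response (TR) construction turns a single trial of
spiking into a time series of binary graphs: entry (j, k) of A(n) is set
iff a structural connection j→k exists, neuron j spikes in time bin n
(bins of width Δt₁ ms), and neuron k spikes strictly within Δt₂ ms after
that presynaptic spike.  Every A(n) is therefore a subgraph of the
structural connectivity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .digraph import DirectedGraph
from .errors import ContractError, ValidationError
from .flag import ParticipationProfile, SimplexTable, build_flag_complex

__all__ = [
    "SpikeTrainSet",
    "PSTHMatrix",
    "CorrelationMatrix",
    "TRSeries",
    "psth",
    "correlation_matrix",
    "correlation_bin_sweep",
    "tr_series",
    "active_simplex_enrichment",
    "edge_participation_correlation",
    "position_pair_correlation",
    "read_spikes_csv",
    "write_spikes_csv",
    "read_spikes_hdf5",
    "write_spikes_hdf5",
]

DEFAULT_PSTH_BIN_MS = 25.0
DEFAULT_DT1_MS = 5.0
DEFAULT_DT2_MS = 10.0


@dataclass
class SpikeTrainSet:
    """Per-neuron, per-trial spike times in ms on [0, duration)."""

    spikes: list[list[np.ndarray]]  # [neuron][trial] -> sorted times
    duration: float
    stimulus_id: str | None = None

    def __post_init__(self) -> None:
        for j, trials in enumerate(self.spikes):
            for t, times in enumerate(trials):
                arr = np.asarray(times, dtype=float)
                if arr.size:
                    if arr.min() < 0 or arr.max() >= self.duration:
                        raise ValidationError(
                            f"neuron {j} trial {t}: spike time outside [0, T)"
                        )
                    if np.any(np.diff(arr) <= 0):
                        raise ValidationError(
                            f"neuron {j} trial {t}: times not strictly increasing"
                        )
                self.spikes[j][t] = arr

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    @property
    def n_trials(self) -> int:
        return len(self.spikes[0]) if self.spikes else 0


@dataclass
class PSTHMatrix:
    """Trial-averaged binned spike counts: neurons × bins."""

    rates: np.ndarray
    bin_size: float
    stimulus_id: str | None = None


@dataclass
class CorrelationMatrix:
    """Normalized covariance R_ij = C_ij / √(C_ii C_jj) of PSTH rows.

    Rows with zero variance (non-responding neurons) are masked invalid;
    their R entries are NaN and excluded from all downstream means.
    """

    R: np.ndarray
    valid_mask: np.ndarray


@dataclass
class TRSeries:
    """Time series of transmission-response graphs.

    ``edge_active[n, e]`` flags structural edge e (in the order of
    ``structure.edges``) as active in time bin n.  The n-th binary
    matrix A(n) is reconstructed on demand.
    """

    edge_active: np.ndarray  # (N, m) bool
    structure: DirectedGraph
    dt1: float
    dt2: float

    @property
    def n_bins(self) -> int:
        return self.edge_active.shape[0]

    def matrix(self, n: int) -> sparse.csr_matrix:
        act = self.structure.edges[self.edge_active[n]]
        return sparse.csr_matrix(
            (np.ones(len(act), dtype=bool), (act[:, 0], act[:, 1])),
            shape=(self.structure.n_vertices, self.structure.n_vertices),
        )

    def active_edges(self, n: int) -> np.ndarray:
        return self.structure.edges[self.edge_active[n]]

    def write_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["dt1"] = self.dt1
            fh.attrs["dt2"] = self.dt2
            fh.create_dataset("edges", data=self.structure.edges)
            fh.create_dataset(
                "edge_active", data=self.edge_active, compression="gzip"
            )


# ---------------------------------------------------------------------- #
# PSTH and correlations
# ---------------------------------------------------------------------- #
def psth(spikes: SpikeTrainSet, bin_size: float = DEFAULT_PSTH_BIN_MS) -> PSTHMatrix:
    """Peri-stimulus time histogram: mean over trials of per-bin spike
    counts, with half-open bins [b·bin, (b+1)·bin)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = int(np.floor(spikes.duration / bin_size))
    edges = np.arange(n_bins + 1) * bin_size
    rates = np.zeros((spikes.n_neurons, n_bins))
    for j, trials in enumerate(spikes.spikes):
        for times in trials:
            rates[j] += np.histogram(times, bins=edges)[0]
    rates /= max(spikes.n_trials, 1)
    return PSTHMatrix(rates, bin_size, spikes.stimulus_id)


def correlation_matrix(
    p: PSTHMatrix, concatenate: list[PSTHMatrix] | None = None
) -> CorrelationMatrix:
    """Normalized covariance of PSTH rows; responses to different stimuli
    may be concatenated along the time axis before correlating."""
    blocks = [p] + list(concatenate or [])
    n = blocks[0].rates.shape[0]
    for b in blocks[1:]:
        if b.rates.shape[0] != n or b.bin_size != blocks[0].bin_size:
            raise ValidationError("concatenated PSTHs must share neurons and bin size")
    rows = np.hstack([b.rates for b in blocks])
    var = rows.var(axis=1)
    valid = var > 0
    R = np.full((n, n), np.nan)
    if valid.sum():
        R_valid = np.corrcoef(rows[valid])
        R[np.ix_(valid, valid)] = np.atleast_2d(R_valid)
    return CorrelationMatrix(R, valid)


def correlation_bin_sweep(
    spikes: SpikeTrainSet, bin_sizes: tuple[float, ...] = (10, 25, 50, 100, 250, 500)
) -> dict[float, CorrelationMatrix]:
    """Sensitivity harness: correlation matrices across PSTH bin sizes."""
    return {b: correlation_matrix(psth(spikes, b)) for b in bin_sizes}


# ---------------------------------------------------------------------- #
# Transmission-response series
# ---------------------------------------------------------------------- #
def tr_series(
    spikes: SpikeTrainSet,
    structure: DirectedGraph,
    dt1: float = DEFAULT_DT1_MS,
    dt2: float = DEFAULT_DT2_MS,
) -> TRSeries:
    """Transmission-response graph series of a single-trial spike set.

    A(n)[j, k] = 1 iff a structural edge j→k exists, some presynaptic
    spike s of j falls in [n·Δt₁, (n+1)·Δt₁), and some spike of k
    follows that same s with a strictly positive gap strictly below Δt₂.
    A spike exactly Δt₂ (or 0) after the presynaptic spike does not
    count.
    """
    if spikes.n_trials != 1:
        raise ContractError("tr_series takes single-trial input; one series per trial")
    if dt1 <= 0 or dt2 <= 0:
        raise ValueError("dt1 and dt2 must be positive")
    if spikes.n_neurons != structure.n_vertices:
        raise ValidationError("spike set and structure disagree on neuron count")
    n_bins = int(np.floor(spikes.duration / dt1))
    m = structure.n_edges
    active = np.zeros((n_bins, m), dtype=bool)
    trains = [trials[0] for trials in spikes.spikes]
    for e, (j, k) in enumerate(map(tuple, structure.edges)):
        pre_t, post_t = trains[j], trains[k]
        if pre_t.size == 0 or post_t.size == 0:
            continue
        # First postsynaptic spike strictly after each presynaptic spike.
        idx = np.searchsorted(post_t, pre_t, side="right")
        ok = idx < post_t.size
        gaps = np.where(ok, post_t[np.minimum(idx, post_t.size - 1)] - pre_t, np.inf)
        transmitted = ok & (gaps < dt2)  # gap > 0 guaranteed by side="right"
        bins = (pre_t[transmitted] // dt1).astype(np.int64)
        bins = bins[bins < n_bins]
        active[bins, e] = True
    return TRSeries(active, structure, dt1, dt2)


# ---------------------------------------------------------------------- #
# Simplex-level analyses
# ---------------------------------------------------------------------- #
def _simplex_edge_incidence(
    table: SimplexTable, structure: DirectedGraph, dims: list[int]
) -> dict[int, sparse.csr_matrix]:
    """For each requested dimension, a (n_simplices × n_edges) incidence
    matrix: simplex σ requires edge e iff e = (vᵢ, vⱼ) for some i < j."""
    edge_index = {tuple(e): i for i, e in enumerate(map(tuple, structure.edges))}
    out = {}
    for d in dims:
        simp = table.simplices(d)
        rows, cols = [], []
        for s_i, row in enumerate(simp):
            verts = [int(v) for v in row]
            for a, b in itertools.combinations(verts, 2):
                rows.append(s_i)
                cols.append(edge_index[(a, b)])
        out[d] = sparse.csr_matrix(
            (np.ones(len(rows), dtype=np.int32), (rows, cols)),
            shape=(len(simp), structure.n_edges),
        )
    return out


def active_simplex_enrichment(
    tr: TRSeries,
    structure: DirectedGraph,
    dims: list[int],
    n_random: int = 10,
    seed: int = 0,
    table: SimplexTable | None = None,
) -> pd.DataFrame:
    """Per time bin: fraction of structural edges active, fraction of
    structural k-simplices whose edges are all active, and the same
    simplex fractions for control graphs with equally many edges drawn
    uniformly from the structural edge set.

    Raw counts and fractions are both emitted (normalization baseline is
    the structural total per dimension).
    """
    if table is None:
        table = build_flag_complex(structure, max_dim=max(dims))
    incidence = _simplex_edge_incidence(table, structure, dims)
    n_required = {d: inc.sum(axis=1).A1 for d, inc in incidence.items()}
    rng = np.random.default_rng(seed)
    m = structure.n_edges
    records = []
    for n in range(tr.n_bins):
        flags = tr.edge_active[n].astype(np.int32)
        n_act = int(flags.sum())
        rec = {
            "bin": n,
            "n_active_edges": n_act,
            "edge_fraction": n_act / m if m else 0.0,
        }
        for d in dims:
            total = incidence[d].shape[0]
            hit = incidence[d] @ flags
            n_simp = int(np.sum(hit == n_required[d])) if total else 0
            rec[f"n_active_simplices_dim{d}"] = n_simp
            rec[f"simplex_fraction_dim{d}"] = n_simp / total if total else np.nan
            ctrl = []
            for _ in range(n_random):
                rand_flags = np.zeros(m, dtype=np.int32)
                rand_flags[rng.choice(m, size=n_act, replace=False)] = 1
                hit_r = incidence[d] @ rand_flags
                ctrl.append(
                    np.sum(hit_r == n_required[d]) / total if total else np.nan
                )
            rec[f"control_fraction_dim{d}"] = float(np.mean(ctrl))
            rec[f"control_std_dim{d}"] = float(np.std(ctrl))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def edge_participation_correlation(
    r: CorrelationMatrix,
    prof: ParticipationProfile,
    min_samples: int = 1000,
) -> pd.DataFrame:
    """Mean spike correlation of connected pairs, grouped by the number
    of maximal simplices the connecting edge belongs to, dimension by
    dimension.  Groups with fewer than ``min_samples`` edges are omitted,
    as are edges with an invalid (non-responding) endpoint."""
    frame = prof.per_edge_maximal_counts
    pre = frame.index.get_level_values("pre").to_numpy()
    post = frame.index.get_level_values("post").to_numpy()
    rvals = r.R[pre, post]
    ok = ~np.isnan(rvals)
    rows = []
    for d in frame.columns:
        counts = frame[d].to_numpy()
        for c in np.unique(counts[counts > 0]):
            sel = ok & (counts == c)
            if sel.sum() >= min_samples:
                rows.append(
                    {
                        "dimension": int(d),
                        "n_maximal": int(c),
                        "mean_R": float(rvals[sel].mean()),
                        "n_edges": int(sel.sum()),
                    }
                )
    return pd.DataFrame(rows, columns=["dimension", "n_maximal", "mean_R", "n_edges"])


PAIR_KINDS = ("first-second", "source-sink", "last-pair")


def position_pair_correlation(
    r: CorrelationMatrix, maximal: SimplexTable
) -> pd.DataFrame:
    """Mean correlation of designated vertex pairs of maximal simplices,
    by simplex dimension: (first, second), (source, sink), and
    (second-to-last, last).  In dimension 1 the three kinds coincide."""
    rows = []
    for d in range(1, maximal.max_dim + 1):
        simp = maximal.simplices(d)
        if len(simp) == 0:
            continue
        pairs = {
            "first-second": (simp[:, 0], simp[:, 1]),
            "source-sink": (simp[:, 0], simp[:, -1]),
            "last-pair": (simp[:, -2], simp[:, -1]),
        }
        for kind in PAIR_KINDS:
            a, b = pairs[kind]
            vals = r.R[a, b]
            vals = vals[~np.isnan(vals)]
            rows.append(
                {
                    "dimension": d,
                    "pair_kind": kind,
                    "mean_R": float(vals.mean()) if vals.size else np.nan,
                    "n_pairs": int(vals.size),
                }
            )
    return pd.DataFrame(rows, columns=["dimension", "pair_kind", "mean_R", "n_pairs"])


# ---------------------------------------------------------------------- #
# Spike I/O
# ---------------------------------------------------------------------- #
def write_spikes_csv(spikes: SpikeTrainSet, path: str | Path) -> None:
    rows = [
        (j, t, time)
        for j, trials in enumerate(spikes.spikes)
        for t, times in enumerate(trials)
        for time in times
    ]
    pd.DataFrame(rows, columns=["neuron_id", "trial", "time_ms"]).to_csv(
        path, index=False
    )


def read_spikes_csv(
    path: str | Path,
    duration: float,
    n_neurons: int | None = None,
    n_trials: int | None = None,
) -> SpikeTrainSet:
    """Read spikes from a (neuron_id, trial, time_ms) CSV."""
    df = pd.read_csv(path)
    required = {"neuron_id", "trial", "time_ms"}
    if not required.issubset(df.columns):
        raise ValidationError(f"spike CSV must have columns {sorted(required)}")
    n_neurons = n_neurons or int(df["neuron_id"].max()) + 1
    n_trials = n_trials or int(df["trial"].max()) + 1
    spikes = [
        [np.empty(0) for _ in range(n_trials)] for _ in range(n_neurons)
    ]
    for (j, t), grp in df.groupby(["neuron_id", "trial"]):
        spikes[int(j)][int(t)] = np.sort(grp["time_ms"].to_numpy(dtype=float))
    return SpikeTrainSet(spikes, duration)


def write_spikes_hdf5(spikes: SpikeTrainSet, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["duration"] = spikes.duration
        fh.attrs["n_neurons"] = spikes.n_neurons
        fh.attrs["n_trials"] = spikes.n_trials
        for j, trials in enumerate(spikes.spikes):
            for t, times in enumerate(trials):
                fh.create_dataset(f"neuron{j}/trial{t}", data=times)


def read_spikes_hdf5(path: str | Path) -> SpikeTrainSet:
    with h5py.File(path, "r") as fh:
        n_neurons = int(fh.attrs["n_neurons"])
        n_trials = int(fh.attrs["n_trials"])
        spikes = [
            [np.asarray(fh[f"neuron{j}/trial{t}"]) for t in range(n_trials)]
            for j in range(n_neurons)
        ]
        return SpikeTrainSet(spikes, float(fh.attrs["duration"]))
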