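# Methods

## Scope and model

`flagtopo` analyzes the topology of directed networks — in particular
neural microcircuits, where an edge is a chemical synapse from a
presynaptic to a postsynaptic neuron — and relates that topology to
spiking activity. The core objects are:

* **Directed graph** `G = (V, E)`: finite, no self-loops, at most one
  edge per ordered pair; reciprocal pairs are allowed. Adjacency
  matrices are oriented rows-presynaptic / columns-postsynaptic.
* **Directed n-simplex**: an ordered tuple `(v₀, …, vₙ)` with an edge
  `vᵢ→vⱼ` for all `i < j`. Equivalently, an all-to-all connected,
  reciprocal-free clique with a unique source `v₀` and sink `vₙ`.
  Because tuples are ordered, `(v₁,v₂,v₃)` and `(v₂,v₁,v₃)` are
  distinct simplices when `v₁` and `v₂` are reciprocally connected.
* **Directed flag complex**: all directed simplices of `G`, closed
  under taking ordered subsets (faces). Maximal simplices are those
  that are faces of nothing larger; their closure regenerates the
  whole complex.
* **Mod-2 homology**: chain groups with one 𝔽₂ basis element per
  simplex; the boundary of an n-simplex is the sum of its n+1
  single-vertex-deletion faces. Betti numbers follow from
  `β₀ = |S₀| − rk(∂₁)`, `βₙ = null(∂ₙ) − rk(∂ₙ₊₁)`, and
  `β_top = null(∂_top)`; the Euler characteristic is the alternating
  sum of simplex counts and equals the alternating sum of Betti
  numbers.

## Algorithms and numerical choices

**Enumeration** is by ordered sink extension: a k-simplex is extended
by every vertex in the intersection of the out-neighborhoods of all
its vertices. Out-neighborhoods are bit-packed into Python integers,
so the intersection is a single AND per extension; each simplex is
generated exactly once and, because extension candidates are visited
in ascending order, each dimension's list is lexicographically
sorted. A configurable simplex-count budget (default 10⁷) aborts
early on dense graphs, naming the dimension reached.

**Maximality** uses an insertion test over all positions: `σ` of
dimension n is non-maximal iff some vertex u can be inserted at
position i, which requires edges `vⱼ→u` for `j < i` and `u→vⱼ` for
`j ≥ i`. Prefix ANDs of out-masks and suffix ANDs of in-masks make
this O(n) bit operations per candidate position. Testing extension
only at the sink would be wrong: `(0,2)` is a face of `(0,1,2)` only
via internal insertion.

**GF(2) ranks** are computed by Gaussian elimination on bit-packed
columns (one Python integer per column, pivot on the highest set
bit). This is exact; no floating point is involved anywhere in the
homology path. Simplex-to-index maps are sorted lexicographically so
boundary matrices are reproducible across runs.

**Coskeleta.** The k-coskeleton keeps all simplices of dimension ≥ k
plus their faces. For k ≥ 1, `Cₖ` and `Cₖ₊₁` and the face relations
of their elements are unchanged, so `βₖ` computed on the k-coskeleton
equals the full complex's `βₖ` while the matrices below dimension
k−1 disappear — the standard route to top Betti numbers of complexes
too large for a full reduction.

**Truncation policy.** A table built with a dimension cap is marked
truncated; Euler characteristics and maximality are refused on it
(the alternating sum and the face-of relation are both undefined
under truncation).

## Null models

All three controls preserve the vertex set and total edge count.

* **ER** (`er_control`): edges drawn uniformly without replacement
  from the n(n−1) ordered off-diagonal pairs. Note this is a
  fixed-edge-count model: expectations of motif counts carry
  finite-population corrections relative to the independent-edge
  binomial model, negligible at n ≳ 100 but visible on toy graphs.
* **PR** (`pr_control`): a uniform subset of a supplied permissive
  candidate graph (a structural prior such as an apposition graph),
  pruned to the reference edge count. The candidate is a parameter;
  the synthetic module provides distance-threshold candidates.
* **GB** (`gb_control`): edges are grouped by (pre-type, post-type)
  and by Euclidean soma-distance bin (default width 75 μm, edges at
  multiples of the width from 0); each connection's target is
  resampled uniformly among same-type vertices in the same distance
  bin from its source. Per-block counts and the binned soma-distance
  histogram of connected pairs are preserved exactly. Resampling may
  return the original target; draws that would create a duplicate
  ordered pair are retried up to 100 times and then the original is
  kept (logged at debug level). Self-loops are excluded from the
  candidate pool up front.

## Activity layer

**PSTH**: trial-averaged spike counts in half-open bins (default
25 ms; a sweep utility covers 10–500 ms). **Correlation**: normalized
covariance `R_ij = C_ij/√(C_ii C_jj)` of PSTH rows, optionally
concatenated across stimuli; zero-variance rows (non-responding
neurons) are masked invalid and excluded from every downstream mean —
the conservative handling of silent cells.

**Transmission-response (TR) series**: for bin width Δt₁ (default
5 ms) and window Δt₂ (default 10 ms), `A(n)[j,k] = 1` iff a structural
edge j→k exists, some presynaptic spike `s` of j lies in
`[nΔt₁, (n+1)Δt₁)`, and some spike of k follows *that same* spike
with a gap strictly between 0 and Δt₂. The strictness is taken
literally: simultaneous spikes and gaps of exactly Δt₂ do not count.
Every TR graph is by construction a subgraph of the structural
connectivity; the implementation is verified against a quadratic
spike-pair oracle.

**Simplex-level analyses**: per-edge counts of the maximal simplices
containing each connection (grouped means of R with a configurable
minimum group size, default 1000, sized for full circuits and
lowered for the smaller synthetic fixtures); mean R for three
designated pairs of each maximal simplex — (first, second),
(source, sink), (second-to-last, last); and per-TR-bin fractions of
active edges and of fully active simplices against matched
random-edge controls (both raw counts and fractions are emitted; the
normalization baseline is the structural total per dimension).

## Synthetic fixtures: what they emulate and what they do not

`make_circuit` samples layered slabs with uniform somata and connects
each ordered pair independently with a distance-decaying kernel
(default `0.15·exp(−d/150 μm)`, two layers of 100 neurons over
400 μm depth and a 300 μm lateral extent, 90% excitatory). These
defaults give flag complexes reaching dimension 3–4 in well under a
second, which is the regime where every analysis in the package can
be cross-checked against brute-force oracles. The generator
reproduces distance dependence and cell-type labels but none of the
morphology-driven specificity of real cortical wiring — passing
tests demonstrate the correctness of the *computations*, not any
biological claim about a particular circuit.

`make_spikes` is an injected-coincidence model, not a dynamical
simulation: each neuron fires homogeneous Poisson background
(default 1 Hz), and each configured ensemble (typically a directed
simplex of a target graph) contributes a Poisson stream of
coactivation events. Each event triggers one spike per participating
member at an ordered cumulative delay (position m fires ~m·jitter
after the event, jitter default 2 ms), so transmission runs
source → sink along the simplex orientation and lands inside the TR
window. Two deliberate dials create the statistical structure the
structure-function analyses are designed to detect: the coactivation
rate of an ensemble scales with its dimension
(`ensembles_from_simplices`, default 0.5 Hz per dimension), so pairs
inside larger cliques share more drive; and per-member participation
probability ramps linearly from source (default 0.6) to sink
(default 1.0), so sink-adjacent pairs share the most input. The
analyses then recover exactly these gradients — increasing pairwise
correlation with simplex dimension, higher correlation for the last
pair than the first pair, and TR simplex fractions above matched
random-edge controls. These are consistency checks of the analysis
pipeline on a generator built to possess the structure, not
independent evidence about biological tissue.

`sample_patch` emulates a multi-patch recording: a 200×200×20 μm box
placed uniformly in the circuit volume, an optional cell-type
filter, independent random discarding of cells (the patching failure
rate, `keep_fraction`), and a cap of 12 simultaneously held cells;
the induced subgraph's simplex census is tallied per experiment.
`keep_fraction` is a plain parameter; no attempt is made to fit it
to any empirical cluster-size distribution.

## Problem sizes

Default test and analysis scales were chosen so that every pipeline
stage admits an independent brute-force check: oracle-equivalence
suites run on graphs of ≤ 8–12 vertices (hundreds of random
instances), null-model sampling statistics use 100-vertex references
over 200 seeds, and the structure-function suite uses the 200-neuron
default circuit with ~1,200 ensembles, 10 trials of 3 s for
correlations and one 2 s trial for the TR series.

## Known limitations

* Homology is mod-2 only: no orientation signs, no torsion, no
  integer/rational homology, no persistence.
* The flag-complex path is pure Python over bitmasks — ample for
  10³–10⁴-vertex sparse graphs, not for 10⁵-node connectomes.
* The motif census is exact labeled-configuration counting, capped at
  5 vertices (3^10 states); there is no isomorphism-class reduction.
* The GB shuffle's keep-original fallback means that on very sparse
  type/distance blocks the output can retain some original targets;
  the distance histogram remains exact either way.
* The spike generator has no refractoriness, adaptation, inhibitory
  dynamics, or membrane biophysics; its correlations come entirely
  from injected common events.
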