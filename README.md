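# flagtopo

Topological analysis of directed networks for systems neuroscience:
directed flag complexes, simplex censuses, mod-2 Betti numbers and
Euler characteristics, density-matched null connectivity models, and a
structure-function layer that maps spike trains onto the network's
clique structure.

In a directed graph (no self-loops, at most one edge per ordered
pair, reciprocal pairs allowed), a **directed n-simplex** is an
ordered tuple (v₀, …, vₙ) with an edge vᵢ→vⱼ for every i < j — an
all-to-all connected clique with a unique source and sink, the motif
through which information flow has an unambiguous direction. The
**directed flag complex** collects all such simplices; its **Betti
numbers** βₙ count the n-dimensional cavities enclosed by simplices in
its geometric realization, computed here over 𝔽₂ from ranks and
nullities of boundary matrices:

    β₀ = |S₀| − rk(∂₁),   βₙ = null(∂ₙ) − rk(∂ₙ₊₁),   χ = Σ (−1)ⁿ|Sₙ| = Σ (−1)ⁿβₙ

The activity layer builds peri-stimulus time histograms, normalized
cross-covariances R_ij = C_ij/√(C_ii C_jj), and **transmission-response
graph** series: per time bin of width Δt₁, the structural subgraph of
edges whose presynaptic neuron spikes in the bin and whose
postsynaptic neuron follows within Δt₂. It then relates spike
correlations to the number, dimension, and position of the directed
simplices a connection or neuron participates in.

Intended users: anyone analyzing directed connectivity data (synthetic
circuits, reconstructed connectomes in edge-list or Matrix Market
form) together with spike data, who wants exact, oracle-tested
topological statistics at the scale of 10²–10⁴ nodes.

## Worked example

```python
from flagtopo import *
from flagtopo.synth import (CircuitSpec, SpikeGenSpec, make_circuit,
                            make_spikes, ensembles_from_simplices)

# 1. Exhaustive motif census on 4 labeled vertices
print(motif_census(4).as_dict())

# 2. Worked homology example: eight directed triangles tiling a sphere
octa = known_complex("octahedron-sphere")
table = build_flag_complex(octa)
print("counts:", table.counts)
print(betti_numbers(boundary_matrices(table)).to_json())

# 3. Structure-function on a synthetic circuit
g = make_circuit(CircuitSpec(seed=3))          # 200-neuron layered circuit
table = build_flag_complex(g)
maxi = maximal_simplices(table, g)
ens = ensembles_from_simplices(maxi, rate_per_dim=0.4)
spikes = make_spikes(SpikeGenSpec(n_neurons=g.n_vertices, duration=3000.0,
                                  n_trials=10, baseline_rate=1.0,
                                  ensembles=ens, seed=11))
r = correlation_matrix(psth(spikes))
print(position_pair_correlation(r, maxi).to_string(index=False))
```

Output:

```
{'k': 4, 'n_total_configurations': 729, 'n_unidirectional': 64, 'n_acyclic': 24, 'n_cyclic': 40}
counts: [6, 12, 8]
{"betti": [1, 0, 1], "chi": 2, "computed_dims": [0, 1, 2]}
 dimension    pair_kind   mean_R  n_pairs
         1 first-second 0.029165      595
         1  source-sink 0.029165      595
         1    last-pair 0.029165      595
         2 first-second 0.083063      629
         2  source-sink 0.086478      629
         2    last-pair 0.100798      629
         3 first-second 0.064523        5
         3  source-sink 0.100379        5
         3    last-pair 0.211035        5
```

Reading the numbers: of the 3⁶ = 729 directed configurations of a
fully connected 4-clique, 64 have no reciprocal pair, and those split
into 24 acyclic configurations (the directed 3-simplices) and 40
containing an oriented cycle. The octahedron graph's flag complex has
6 vertices, 12 edges, and 8 triangles enclosing a single 2-dimensional
cavity (β₂ = 1, χ = 2 — a combinatorial 2-sphere); adding any edge
between an antipodal pair fills the cavity. In the spike analysis,
mean pairwise correlation grows with the dimension of the maximal
simplex containing the pair, and within simplices of dimension ≥ 2
the sink-adjacent pair (last two neurons, which share the most common
drive) is more correlated than the source-adjacent pair.

A CLI wraps the same operations for shell pipelines, e.g.:

```
flagtopo motif-census --k 4 --out motifs.json
flagtopo fixtures --kind complex --name octahedron-sphere --out octa.mtx
flagtopo betti --in octa.mtx --out betti.json
flagtopo nullmodel --kind er --seed 7 --in ref.mtx --out ctrl.mtx
```

Every command writes a JSON manifest (parameters, seeds, version,
input checksums) beside its output.

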