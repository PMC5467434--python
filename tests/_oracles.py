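"""Independent brute-force oracles used to validate the fast paths.

These deliberately share no code with the package implementation:
enumeration is over all ordered vertex tuples, cycle detection is a
path search over edge sequences, and TR transmission checks all spike
pairs quadratically.
"""

import itertools

import numpy as np


def brute_force_flag_simplices(n_vertices, edge_set, max_dim=None):
    """All directed simplices by checking every ordered vertex tuple."""
    top = n_vertices - 1 if max_dim is None else max_dim
    by_dim = [sorted((v,) for v in range(n_vertices))]
    for d in range(1, top + 1):
        found = []
        for combo in itertools.combinations(range(n_vertices), d + 1):
            for perm in itertools.permutations(combo):
                if all(
                    (perm[i], perm[j]) in edge_set
                    for i in range(d + 1)
                    for j in range(i + 1, d + 1)
                ):
                    found.append(perm)
        if not found:
            break
        by_dim.append(sorted(found))
    return by_dim


def has_oriented_cycle(n_vertices, edge_set):
    """Path search: does any vertex reach itself along directed edges?"""
    adj = {v: [] for v in range(n_vertices)}
    for u, v in edge_set:
        adj[u].append(v)
    for start in range(n_vertices):
        stack = [start]
        seen = set()
        while stack:
            node = stack.pop()
            for nxt in adj[node]:
                if nxt == start:
                    return True
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
    return False


def brute_force_tr_edges(trains, edge_set, dt1, dt2, n_bins):
    """Active (bin, edge) pairs by checking all spike pairs O(s²)."""
    active = set()
    for (j, k) in edge_set:
        for s in trains[j]:
            for t in trains[k]:
                if 0 < t - s < dt2:
                    b = int(s // dt1)
                    if b < n_bins:
                        active.add((b, (j, k)))
    return active


def random_graph(n, p, rng):
    """Uniform directed graph: each ordered off-diagonal pair with prob p."""
    edges = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return n, set(edges)


def directionality_by_summation(n_vertices, edge_set):
    indeg = [0] * n_vertices
    outdeg = [0] * n_vertices
    for u, v in edge_set:
        outdeg[u] += 1
        indeg[v] += 1
    return sum((indeg[v] - outdeg[v]) ** 2 for v in range(n_vertices))
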