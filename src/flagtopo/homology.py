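"""Mod-2 simplicial homology of directed flag complexes.

The chain complex over 𝔽₂ has one basis element per simplex; the
boundary of an n-simplex σ is the sum of its n+1 faces σ⁰ + … + σⁿ,
where the i-th face removes vertex v_{n−i}.  Betti numbers follow from
ranks and nullities of the boundary matrices:

    β₀ = |S₀| − rk(∂₁)
    βₙ = null(∂ₙ) − rk(∂ₙ₊₁)      (1 ≤ n < top)
    β_top = null(∂_top)

Ranks are computed by Gaussian elimination on bit-packed columns, which
is exact over 𝔽₂ (no orientation signs are needed mod 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .errors import ContractError
from .flag import SimplexTable, coskeleton

__all__ = [
    "ChainComplexGF2",
    "BettiProfile",
    "boundary_matrices",
    "betti_numbers",
    "euler_characteristic",
    "top_betti_via_coskeleton",
    "gf2_rank",
]


@dataclass
class ChainComplexGF2:
    """Boundary matrices of a simplicial complex over the two-element field.

    ``boundary_matrices[n-1]`` is Dₙ with shape |Sₙ₋₁| × |Sₙ| for
    n = 1 … max_dim; ``basis_index[d]`` maps each d-simplex tuple to its
    row/column position (lexicographic order of vertex tuples).
    """

    boundary_matrices: list[sparse.csc_matrix]
    basis_index: list[dict[tuple[int, ...], int]]
    n_simplices: list[int]

    @property
    def max_dim(self) -> int:
        return len(self.n_simplices) - 1


@dataclass
class BettiProfile:
    """Betti numbers β₀ … β_top and the Euler characteristic χ.

    When all Betti numbers are computed, χ = Σ (−1)ⁿ βₙ; ``computed_dims``
    lists the dimensions for which βₙ is available.
    """

    betti: list[int]
    euler_characteristic: int
    computed_dims: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.computed_dims:
            self.computed_dims = list(range(len(self.betti)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "betti": self.betti,
                "chi": self.euler_characteristic,
                "computed_dims": self.computed_dims,
            }
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


# ---------------------------------------------------------------------- #
def _check_face_closed(tuple_sets: list[set[tuple[int, ...]]]) -> None:
    for d in range(1, len(tuple_sets)):
        for sigma in tuple_sets[d]:
            for i in range(len(sigma)):
                face = sigma[:i] + sigma[i + 1:]
                if face not in tuple_sets[d - 1]:
                    raise ContractError(
                        f"complex is not face-closed: face {face} of {sigma} missing"
                    )


def boundary_matrices(s: SimplexTable) -> ChainComplexGF2:
    """Boundary matrices Dₙ of a face-closed simplex table.

    Entry (τ, σ) of Dₙ is 1 iff τ is one of the n+1 faces of σ obtained
    by deleting a single vertex.  Simplices are indexed lexicographically
    by vertex tuple for reproducibility.
    """
    tuple_sets = s.as_tuple_sets()
    _check_face_closed(tuple_sets)
    basis: list[dict[tuple[int, ...], int]] = [
        {t: i for i, t in enumerate(sorted(ts))} for ts in tuple_sets
    ]
    mats: list[sparse.csc_matrix] = []
    for d in range(1, s.max_dim + 1):
        rows, cols = [], []
        for sigma, j in basis[d].items():
            for i in range(len(sigma)):
                face = sigma[:i] + sigma[i + 1:]
                rows.append(basis[d - 1][face])
                cols.append(j)
        mats.append(
            sparse.csc_matrix(
                (np.ones(len(rows), dtype=np.uint8), (rows, cols)),
                shape=(len(basis[d - 1]), len(basis[d])),
            )
        )
    return ChainComplexGF2(mats, basis, [len(b) for b in basis])


def gf2_rank(mat: sparse.spmatrix) -> int:
    """Rank of a binary matrix over 𝔽₂ via column elimination on
    bit-packed columns (each column one Python integer)."""
    csc = mat.tocsc()
    pivots: dict[int, int] = {}  # leading-bit position -> column value
    rank = 0
    for j in range(csc.shape[1]):
        col = 0
        for r in csc.indices[csc.indptr[j]:csc.indptr[j + 1]]:
            col ^= 1 << int(r)
        while col:
            lead = col.bit_length() - 1
            if lead in pivots:
                col ^= pivots[lead]
            else:
                pivots[lead] = col
                rank += 1
                break
    return rank


def betti_numbers(c: ChainComplexGF2) -> BettiProfile:
    """All Betti numbers of a chain complex, by rank/nullity of its
    boundary matrices, together with χ = Σ (−1)ⁿ |Sₙ|."""
    counts = c.n_simplices
    top = c.max_dim
    ranks = [gf2_rank(d) for d in c.boundary_matrices]  # rk(D_1) .. rk(D_top)
    betti = []
    for n in range(top + 1):
        rk_n = ranks[n - 1] if n >= 1 else 0
        rk_next = ranks[n] if n < top else 0
        null_n = counts[n] - rk_n
        betti.append(null_n - rk_next)
    chi = sum((-1) ** n * cnt for n, cnt in enumerate(counts))
    return BettiProfile(betti, chi)


def euler_characteristic(s: SimplexTable) -> int:
    """χ(S) = Σₙ (−1)ⁿ |Sₙ|.  Refuses dimension-truncated tables, whose
    alternating sum would be meaningless."""
    if s.truncated:
        raise ContractError("Euler characteristic undefined on a truncated table")
    return sum((-1) ** n * cnt for n, cnt in enumerate(s.counts))


def top_betti_via_coskeleton(s: SimplexTable, k: int) -> int:
    """βₖ computed on the k-coskeleton of ``s``.

    The k-coskeleton contains every simplex of dimension ≥ k and all
    their faces, so Cₖ and Cₖ₊₁ — and hence null(∂ₖ) and rk(∂ₖ₊₁) — agree
    with the full complex; only the (cheaper) row space of ∂ₖ shrinks.
    This is the standard trick for computing the top nonzero Betti
    numbers of complexes too large for a full reduction.
    """
    if k < 1:
        raise ValueError("top_betti_via_coskeleton requires k >= 1")
    if k > s.max_dim:
        return 0
    cs = coskeleton(s, k)
    c = boundary_matrices(cs)
    rk_k = gf2_rank(c.boundary_matrices[k - 1])
    rk_next = (
        gf2_rank(c.boundary_matrices[k]) if k < c.max_dim else 0
    )
    return c.n_simplices[k] - rk_k - rk_next
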