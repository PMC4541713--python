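"""Clique-complex construction and exact simplicial homology.

The coupling graph :math:`\\mathcal{G}` generated by the non-zero pairwise
couplings is completed to its clique (flag) complex :math:`\\mathcal{C}`:
the n-simplices are exactly the (n+1)-cliques of the graph, so the graph is
the 1-skeleton of the complex.  Betti numbers are computed exactly from the
ranks of the simplicial boundary operators, by default over GF(2) (cheap
bitset linear algebra, and the natural field for a model whose degrees of
freedom are Z2-valued), optionally over the rationals for torsion detection.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIM = 4


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BettiVector:
    """Betti numbers b_0 ... b_max_dim with the coefficient field used."""

    b: tuple[int, ...]
    coefficient_field: str = "GF2"  # "GF2" or "rationals"

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.b):
            raise ValueError("Betti numbers must be non-negative")
        if self.coefficient_field not in ("GF2", "rationals"):
            raise ValueError(f"unknown coefficient field {self.coefficient_field!r}")

    def __len__(self) -> int:
        return len(self.b)

    def __getitem__(self, i: int) -> int:
        return self.b[i]

    def padded(self, length: int) -> tuple[int, ...]:
        return tuple(self.b) + (0,) * max(0, length - len(self.b))


@dataclass
class SimplicialComplex:
    """A finite simplicial complex on vertices 0..N-1.

    ``simplices`` maps dimension -> lexicographically sorted list of sorted
    vertex tuples.  The complex is closed under faces by construction.
    """

    simplices: dict[int, list[tuple[int, ...]]]
    N: int
    max_dim: int = field(default=0)

    def __post_init__(self) -> None:
        self.max_dim = max(self.simplices) if self.simplices else -1
        self._index: dict[int, dict[tuple[int, ...], int]] = {
            d: {s: i for i, s in enumerate(sxs)} for d, sxs in self.simplices.items()
        }

    def n_simplices(self, dim: int) -> int:
        return len(self.simplices.get(dim, []))

    def has_simplex(self, verts: tuple[int, ...]) -> bool:
        verts = tuple(sorted(verts))
        return verts in self._index.get(len(verts) - 1, {})

    def euler_characteristic(self) -> int:
        return sum((-1) ** d * len(sxs) for d, sxs in self.simplices.items())

    def graph(self) -> nx.Graph:
        """The 1-skeleton as a networkx graph (isolated vertices included)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(self.simplices.get(1, []))
        return g

    def validate(self) -> None:
        """Check closure under faces and vertex-range invariants."""
        for d, sxs in self.simplices.items():
            for s in sxs:
                if list(s) != sorted(set(s)):
                    raise ValueError(f"simplex {s} is not strictly increasing")
                if s[0] < 0 or s[-1] >= self.N:
                    raise ValueError(f"simplex {s} has vertices outside 0..{self.N - 1}")
                if d >= 1:
                    for face in itertools.combinations(s, d):
                        if face not in self._index.get(d - 1, {}):
                            raise ValueError(f"face {face} of {s} is missing")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {"N": self.N, "simplices": {str(d): [list(s) for s in sxs]
                                              for d, sxs in self.simplices.items()}}
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SimplicialComplex":
        payload = json.loads(text)
        simplices = {int(d): [tuple(s) for s in sxs]
                     for d, sxs in payload["simplices"].items()}
        return cls(simplices=simplices, N=int(payload["N"]))


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def clique_complex(graph: nx.Graph | list[tuple[int, int]], N: int | None = None,
                   max_dim: int = DEFAULT_MAX_DIM) -> SimplicialComplex:
    """Complete a simple graph to its clique (flag) complex.

    Simplices of dimension n are the (n+1)-cliques, enumerated up to
    ``max_dim`` and stored in lexicographic order (reproducible bit-for-bit).
    Capping is logged because it truncates homology above ``max_dim``.
    """
    if max_dim < 1:
        raise ValueError("max_dim must be >= 1")
    if isinstance(graph, nx.Graph):
        g = graph
        if N is None:
            N = (max(g.nodes) + 1) if g.number_of_nodes() else 0
    else:
        edges = list(graph)
        g = nx.Graph()
        g.add_edges_from(edges)
        if N is None:
            N = (max(g.nodes) + 1) if g.number_of_nodes() else 0
    g = nx.Graph(g)
    g.add_nodes_from(range(N))
    if any(u == v for u, v in g.edges):
        raise ValueError("self-loops are not allowed")
    if any(v < 0 or v >= N for v in g.nodes):
        raise ValueError("vertex ids must lie in 0..N-1")

    simplices: dict[int, list[tuple[int, ...]]] = {0: [(v,) for v in range(N)]}
    truncated = False
    for clique in nx.enumerate_all_cliques(g):
        d = len(clique) - 1
        if d == 0:
            continue
        if d > max_dim:
            truncated = True
            break  # enumerate_all_cliques yields by increasing size
        simplices.setdefault(d, []).append(tuple(sorted(clique)))
    for d in simplices:
        simplices[d].sort()
    if truncated:
        logger.info("clique complex truncated at max_dim=%d; higher Betti "
                    "numbers are not represented", max_dim)
    return SimplicialComplex(simplices=simplices, N=N)


# ---------------------------------------------------------------------------
# Homology
# ---------------------------------------------------------------------------

def boundary_matrix(complex: SimplicialComplex, n: int) -> np.ndarray:
    """Boundary operator ∂_n over GF(2), shape (#(n-1)-simplices, #n-simplices).

    Rows/columns follow the lexicographic simplex ordering, so the matrix is
    reproducible bit-for-bit.  The column of an n-simplex has ones exactly at
    its n+1 facets.
    """
    if n < 1 or n > complex.max_dim:
        raise ValueError(f"n={n} out of range 1..{complex.max_dim}")
    rows = complex._index.get(n - 1, {})
    cols = complex.simplices.get(n, [])
    mat = np.zeros((len(rows), len(cols)), dtype=np.uint8)
    for j, s in enumerate(cols):
        for face in itertools.combinations(s, n):
            mat[rows[face], j] = 1
    return mat


def _gf2_rank_from_columns(cols: list[int]) -> int:
    """Rank over GF(2) of a matrix given as a list of column bitmasks."""
    pivots: dict[int, int] = {}  # pivot row -> column bitmask
    rank = 0
    for col in cols:
        while col:
            p = col.bit_length() - 1
            if p in pivots:
                col ^= pivots[p]
            else:
                pivots[p] = col
                rank += 1
                break
    return rank


def _boundary_columns_bits(complex: SimplicialComplex, n: int) -> list[int]:
    rows = complex._index.get(n - 1, {})
    out = []
    for s in complex.simplices.get(n, []):
        bits = 0
        for face in itertools.combinations(s, n):
            bits |= 1 << rows[face]
        out.append(bits)
    return out


def signed_boundary_matrix(complex: SimplicialComplex, n: int) -> np.ndarray:
    """Integer boundary operator with the usual alternating signs:
    ∂[v_0..v_n] = Σ_i (-1)^i [v_0..v̂_i..v_n]."""
    if n < 1 or n > complex.max_dim:
        raise ValueError(f"n={n} out of range 1..{complex.max_dim}")
    rows = complex._index.get(n - 1, {})
    cols = complex.simplices.get(n, [])
    mat = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for j, s in enumerate(cols):
        for i in range(n + 1):
            face = s[:i] + s[i + 1:]
            mat[rows[face], j] = (-1) ** i
    return mat


def _rational_rank(mat: np.ndarray) -> int:
    import sympy

    if mat.size == 0:
        return 0
    return sympy.Matrix(mat.astype(int)).rank()


def betti_numbers(complex: SimplicialComplex,
                  coefficient_field: str = "GF2") -> BettiVector:
    """Exact Betti numbers b_0..b_max_dim from boundary-operator ranks.

    b_n = dim ker ∂_n - rank ∂_{n+1}; b_0 counts connected components.
    Over GF(2) the ranks are computed with bitset Gaussian elimination; over
    the rationals with exact sympy linear algebra (slower, torsion-aware).
    """
    top = max(complex.max_dim, 0)
    ranks = {0: 0}
    for n in range(1, top + 1):
        if coefficient_field == "GF2":
            ranks[n] = _gf2_rank_from_columns(_boundary_columns_bits(complex, n))
        else:
            ranks[n] = _rational_rank(signed_boundary_matrix(complex, n))
    ranks[top + 1] = 0
    b = []
    for n in range(top + 1):
        n_simp = complex.n_simplices(n)
        b.append(n_simp - ranks[n] - ranks[n + 1])
    return BettiVector(b=tuple(b), coefficient_field=coefficient_field)


def poincare_polynomial(betti: BettiVector) -> list[int]:
    """Coefficients of the Poincaré polynomial Σ b_n t^n (index = degree)."""
    return list(betti.b)


def evaluate_polynomial(coefficients: list[int], t: float) -> float:
    """Evaluate Σ c_n t^n; t=1 gives the total Betti number, t=-1 the Euler
    characteristic."""
    return float(sum(c * t ** n for n, c in enumerate(coefficients)))


# ---------------------------------------------------------------------------
# 1-skeleton I/O
# ---------------------------------------------------------------------------

def write_edges_tsv(complex: SimplicialComplex, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\n")
        for (u, v) in complex.simplices.get(1, []):
            fh.write(f"{u}\t{v}\n")
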