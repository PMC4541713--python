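"""Persistent homology of antibody-concentration data.

Trajectory matrices (antibodies × timepoints) are turned into a proximity
structure via a correlation distance d_ij = 1 - ρ_ij (anti-correlated
antibodies are maximally far apart), a Vietoris–Rips filtration is built on
the distance matrix, and its persistence over GF(2) summarises the
topology of the data at every proximity scale at once.  The empirical
Betti vector used for model comparison is read off at the midpoint of the
longest scale interval on which the whole Betti vector is constant (the
plateau rule) — long-lived classes are topological signal, short-lived
ones noise.

Persistence is computed with the standard boundary-matrix reduction,
dimension by dimension, with columns in filtration order and GF(2) columns
held as integer bitsets: an (n+1)-simplex whose reduced column has pivot
row σ kills the n-class born with σ, and unpaired positive simplices carry
essential (infinite) classes.  Exact and deterministic for a fixed input.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simplicial import BettiVector

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIM = 2


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal."""

    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        self.d = d

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.d).to_csv(path, index=False, header=False)

    @classmethod
    def from_csv(cls, path: str) -> "DistanceMatrix":
        return cls(pd.read_csv(path, header=None).to_numpy(dtype=float))


def correlation_distance(trajectories, absolute: bool = False) -> DistanceMatrix:
    """d_ij = 1 - ρ_ij (or 1 - |ρ_ij|) from row-wise sample correlations.

    Rows with zero variance (constant trajectories) get ρ := 0 against all
    other rows — distance 1 — with a warning, rather than an error.
    """
    X = np.asarray(trajectories, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 antibodies (rows)")
    if X.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = X.std(axis=1)
    flat = np.where(sd == 0)[0]
    if len(flat):
        logger.warning("%d zero-variance rows; their correlations are set to 0",
                       len(flat))
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(X)
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    if absolute:
        rho = np.abs(rho)
    d = np.clip(1.0 - rho, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d=d)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

@dataclass
class PersistenceDiagram:
    """(dimension, birth, death) triples; death is math.inf for essential
    classes."""

    points: list[tuple[int, float, float]]

    def __post_init__(self) -> None:
        for dim, b, d in self.points:
            if math.isfinite(d) and d < b:
                raise ValueError(f"death {d} before birth {b} in dim {dim}")

    def in_dimension(self, dim: int) -> list[tuple[float, float]]:
        return [(b, d) for dd, b, d in self.points if dd == dim]

    def max_dimension(self) -> int:
        return max((dd for dd, _, _ in self.points), default=0)

    def to_csv(self, path: str) -> None:
        rows = [(dim, b, "inf" if math.isinf(d) else d)
                for dim, b, d in self.points]
        pd.DataFrame(rows, columns=["dim", "birth", "death"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "PersistenceDiagram":
        df = pd.read_csv(path)
        pts = [(int(r["dim"]), float(r["birth"]),
                math.inf if str(r["death"]) == "inf" else float(r["death"]))
               for _, r in df.iterrows()]
        return cls(points=pts)


def _rips_simplices(d: np.ndarray, max_dim: int):
    """Filtration-sorted simplices up to dimension max_dim+1.

    Returns per dimension a list of (filtration_value, vertex_tuple) sorted
    by (value, vertices); the filtration value of a simplex is the largest
    pairwise distance among its vertices.
    """
    n = d.shape[0]
    by_dim: list[list[tuple[float, tuple[int, ...]]]] = []
    by_dim.append(sorted((0.0, (v,)) for v in range(n)))
    for dim in range(1, max_dim + 2):
        sxs = []
        for verts in itertools.combinations(range(n), dim + 1):
            idx = np.array(verts)
            f = float(d[np.ix_(idx, idx)].max())
            sxs.append((f, verts))
        sxs.sort()
        by_dim.append(sxs)
    return by_dim


def rips_persistence(d: DistanceMatrix, max_dim: int = 1) -> PersistenceDiagram:
    """Vietoris–Rips persistence over GF(2) up to homological dimension
    ``max_dim`` (the full complete filtration; the complex is built one
    dimension higher so that deaths in dimension max_dim are seen).
    """
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    dm = d.d
    by_dim = _rips_simplices(dm, max_dim)
    points: list[tuple[int, float, float]] = []
    # positions[k]: simplex tuple -> filtration-order index among k-simplices
    positions = [{s: i for i, (_, s) in enumerate(by_dim[k])}
                 for k in range(len(by_dim))]
    paired_positive: list[set] = [set() for _ in range(len(by_dim))]
    negatives: list[set] = [set() for _ in range(len(by_dim))]
    for k in range(1, len(by_dim)):
        rows = positions[k - 1]
        row_f = [f for f, _ in by_dim[k - 1]]
        pivots: dict[int, int] = {}  # pivot row -> reduced column bitset
        for idx, (f, s) in enumerate(by_dim[k]):
            col = 0
            for face in itertools.combinations(s, k):
                col |= 1 << rows[face]
            while col:
                p = col.bit_length() - 1
                if p in pivots:
                    col ^= pivots[p]
                else:
                    # column survives: this k-simplex is negative, it kills
                    # the (k-1)-class created by the pivot-row simplex
                    pivots[p] = col
                    negatives[k].add(idx)
                    paired_positive[k - 1].add(p)
                    if k - 1 <= max_dim:
                        points.append((k - 1, row_f[p], f))
                    break
    # essential classes: positive k-simplices never killed by a (k+1)-column
    for k in range(0, max_dim + 1):
        for idx, (f, _) in enumerate(by_dim[k]):
            if idx in negatives[k] or idx in paired_positive[k]:
                continue
            points.append((k, f, math.inf))
    points.sort(key=lambda t: (t[0], t[1], t[2]))
    return PersistenceDiagram(points=points)


# ---------------------------------------------------------------------------
# Betti extraction and comparison
# ---------------------------------------------------------------------------

def betti_at_scale(diagram: PersistenceDiagram, t: float,
                   max_dim: int | None = None) -> BettiVector:
    """Betti vector at scale t: bars with birth <= t < death."""
    if max_dim is None:
        max_dim = diagram.max_dimension()
    b = [0] * (max_dim + 1)
    for dim, birth, death in diagram.points:
        if dim <= max_dim and birth <= t < death:
            b[dim] += 1
    return BettiVector(b=tuple(b))


def betti_at_plateau(diagram: PersistenceDiagram, max_dim: int | None = None
                     ) -> tuple[BettiVector, tuple[float, float]]:
    """Betti vector on the longest scale interval of constant full Betti
    vector, read at the interval midpoint; the interval is returned too.

    The scan runs over [0, t_max] with t_max the largest finite birth/death
    in the diagram; ties go to the earliest interval.  A diagram with no
    finite events (a single point) has one all-scale plateau.
    """
    if not diagram.points:
        raise ValueError("empty persistence diagram")
    if max_dim is None:
        max_dim = diagram.max_dimension()
    finite = sorted({v for _, b, d in diagram.points
                     for v in (b, d) if math.isfinite(v)})
    if not finite or finite[-1] == 0:
        return betti_at_scale(diagram, 0.0, max_dim), (0.0, math.inf)
    events = sorted(set([0.0] + finite))
    # Betti vector on each inter-event interval, merging adjacent intervals
    # on which the vector does not change
    segments: list[list] = []  # [start, end, betti]
    for a, b in zip(events, events[1:]):
        bv = betti_at_scale(diagram, (a + b) / 2.0, max_dim)
        if segments and segments[-1][2].b == bv.b:
            segments[-1][1] = b
        else:
            segments.append([a, b, bv])
    best = max(segments, key=lambda seg: seg[1] - seg[0])
    return best[2], (best[0], best[1])


def compare_betti(b_model: BettiVector, b_data: BettiVector) -> tuple[int, bool]:
    """L1 distance between Betti vectors after zero-padding; match iff 0."""
    L = max(len(b_model), len(b_data))
    pm, pd_ = b_model.padded(L), b_data.padded(L)
    dist = int(sum(abs(a - b) for a, b in zip(pm, pd_)))
    return dist, dist == 0
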