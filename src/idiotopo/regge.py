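"""Two-dimensional Z2 Regge calculus on small closed triangulations.

Space is a piecewise-flat simplicial surface whose squared edge lengths are
restricted to two values, q_l = 1 + l*sigma_l with sigma_l = ±1 and
amplitude 0 <= l < 1 (so q_l > 0 always).  Curvature is concentrated at the
vertices as deficit angles d(v) = 2π - Σ (incident triangle angles), and
the discretized action is

    A(q) = x ( Σ_triangles area - ζ Σ_vertices d(v) · V⁰ ),   V⁰ := 1,

so small volumes and large curvature lower the action (x, ζ > 0).  The
state sum enumerates all 2^𝒩 sign assignments over the 𝒩 edges, weighting
each by the simplicial measure Π_l q_l^{-α} and keeping only configurations
that satisfy every triangle inequality (the F(q) indicator).

Because every Euclidean triangle's angles sum to π, the total deficit of a
valid configuration is the combinatorial Gauss–Bonnet constant 2πχ — a
strong correctness check exercised in the test suite.

The dictionary σ_l = 2 c_l - 1 identifies edge signs with binary antibody
concentrations when the edge count equals the network size; conversion
helpers are provided without asserting a full coupling↔geometry mapping.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_EDGE_CAP = 24


# ---------------------------------------------------------------------------
# Triangulations
# ---------------------------------------------------------------------------

@dataclass
class Triangulation2D:
    """Closed triangulated surface: every edge borders exactly 2 triangles."""

    n_vertices: int
    triangles: list[tuple[int, int, int]]
    edges: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        tris = [tuple(sorted(t)) for t in self.triangles]
        if any(len(set(t)) != 3 for t in tris):
            raise ValueError("triangles must have 3 distinct vertices")
        self.triangles = tris
        count: dict[tuple[int, int], int] = {}
        for t in tris:
            for e in itertools.combinations(t, 2):
                count[e] = count.get(e, 0) + 1
        bad = [e for e, c in count.items() if c != 2]
        if bad:
            raise ValueError(f"not a closed surface: edges {bad[:5]} are not in "
                             "exactly 2 triangles")
        self.edges = sorted(count)
        if self.euler_characteristic() % 2 != 0:
            raise ValueError("Euler characteristic of a closed surface is even")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + len(self.triangles)

    def edge_index(self) -> dict[tuple[int, int], int]:
        return {e: i for i, e in enumerate(self.edges)}

    def triangle_edges(self) -> list[tuple[int, int, int]]:
        """For each triangle (a,b,c): indices of edges (b,c), (a,c), (a,b) —
        edge j is opposite vertex j of the triangle."""
        idx = self.edge_index()
        out = []
        for a, b, c in self.triangles:
            out.append((idx[(b, c)], idx[(a, c)], idx[(a, b)]))
        return out


def tetrahedron() -> Triangulation2D:
    return Triangulation2D(4, list(itertools.combinations(range(4), 3)))


def octahedron() -> Triangulation2D:
    """Boundary of the octahedron: vertex pairs (0,1), (2,3), (4,5) are
    antipodal; every other pair is an edge."""
    tris = [(a, b, c) for a in (0, 1) for b in (2, 3) for c in (4, 5)]
    return Triangulation2D(6, tris)


def torus16() -> Triangulation2D:
    """8-vertex, 16-triangle torus: cyclic triangulation with triangles
    {i, i+1, i+3} and {i, i+2, i+3} mod 8 (χ = 0, each vertex link a
    6-cycle)."""
    tris = []
    for i in range(8):
        tris.append(tuple(sorted((i, (i + 1) % 8, (i + 3) % 8))))
        tris.append(tuple(sorted((i, (i + 2) % 8, (i + 3) % 8))))
    return Triangulation2D(8, tris)


# ---------------------------------------------------------------------------
# OFF I/O (combinatorial: coordinates are placeholders)
# ---------------------------------------------------------------------------

def write_off(tri: Triangulation2D, path: str,
              coordinates: np.ndarray | None = None) -> None:
    if coordinates is None:
        coordinates = np.zeros((tri.n_vertices, 3))
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{tri.n_vertices} {len(tri.triangles)} {tri.n_edges}\n")
        for xyz in coordinates:
            fh.write(" ".join(f"{v:g}" for v in xyz) + "\n")
        for t in tri.triangles:
            fh.write("3 " + " ".join(str(v) for v in t) + "\n")


def read_off(path: str) -> Triangulation2D:
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                tokens.extend(line.split())
    if tokens[0] != "OFF":
        raise ValueError(f"{path}: not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4 + 3 * nv  # skip counts line (3 ints) and vertex coordinates
    tris = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise ValueError(f"{path}: face with {k} vertices; need triangles")
        tris.append(tuple(int(t) for t in tokens[pos + 1:pos + 4]))
        pos += k + 1
    return Triangulation2D(nv, tris)


# ---------------------------------------------------------------------------
# Edge configurations and geometry
# ---------------------------------------------------------------------------

@dataclass
class Z2EdgeConfig:
    """Sign per edge with squared lengths q_l = 1 + l·σ_l."""

    sigma: np.ndarray
    l_amp: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=int)
        if not np.all(np.isin(self.sigma, (-1, 1))):
            raise ValueError("sigma entries must be ±1")
        if not 0 <= self.l_amp < 1:
            raise ValueError("edge-length amplitude must lie in [0, 1)")

    @property
    def q(self) -> np.ndarray:
        return 1.0 + self.l_amp * self.sigma

    def is_valid(self, tri: Triangulation2D) -> bool:
        """F(q): every triangle satisfies the strict triangle inequality."""
        lengths = np.sqrt(self.q)
        for e1, e2, e3 in tri.triangle_edges():
            a, b, c = sorted((lengths[e1], lengths[e2], lengths[e3]))
            if a + b <= c:
                return False
        return True


def sigma_from_state(c) -> np.ndarray:
    """σ = 2c - 1: binary concentrations to edge signs."""
    c = np.asarray(c, dtype=int)
    if not np.all(np.isin(c, (0, 1))):
        raise ValueError("concentrations must be 0/1")
    return 2 * c - 1


def state_from_sigma(sigma) -> np.ndarray:
    """c = (σ + 1)/2: edge signs to binary concentrations."""
    sigma = np.asarray(sigma, dtype=int)
    if not np.all(np.isin(sigma, (-1, 1))):
        raise ValueError("signs must be ±1")
    return (sigma + 1) // 2


def triangle_geometry(q1: float, q2: float, q3: float
                      ) -> tuple[float, tuple[float, float, float]]:
    """Area (Heron) and interior angles (law of cosines) from squared edge
    lengths; the angle at position i is opposite edge i.  Raises if the
    strict triangle inequality fails (the F(q) = 0 case)."""
    if min(q1, q2, q3) <= 0:
        raise ValueError("squared edge lengths must be positive")
    a, b, c = math.sqrt(q1), math.sqrt(q2), math.sqrt(q3)
    s1, s2, s3 = sorted((a, b, c))
    if s1 + s2 <= s3:
        raise ValueError(f"triangle inequality violated for lengths "
                         f"({a:g}, {b:g}, {c:g})")
    s = 0.5 * (a + b + c)
    area = math.sqrt(s * (s - a) * (s - b) * (s - c))
    ang_a = math.acos((q2 + q3 - q1) / (2 * b * c))
    ang_b = math.acos((q1 + q3 - q2) / (2 * a * c))
    ang_c = math.acos((q1 + q2 - q3) / (2 * a * b))
    return area, (ang_a, ang_b, ang_c)


def deficit_angles(tri: Triangulation2D, config: Z2EdgeConfig) -> np.ndarray:
    """d(v) = 2π - Σ angles at v over the triangles incident to v."""
    if not config.is_valid(tri):
        raise ValueError("configuration violates a triangle inequality")
    q = config.q
    deficits = np.full(tri.n_vertices, 2 * math.pi)
    for (verts, eidx) in zip(tri.triangles, tri.triangle_edges()):
        _, angles = triangle_geometry(q[eidx[0]], q[eidx[1]], q[eidx[2]])
        for v, ang in zip(verts, angles):
            deficits[v] -= ang
    return deficits


def regge_action(tri: Triangulation2D, config: Z2EdgeConfig,
                 x: float, zeta: float) -> float:
    """A = x (Σ areas - ζ Σ_v d(v)·V⁰) with the point volume V⁰ := 1."""
    if x <= 0 or zeta < 0:
        raise ValueError("need x > 0 and zeta >= 0")
    q = config.q
    total_area = 0.0
    for eidx in tri.triangle_edges():
        area, _ = triangle_geometry(q[eidx[0]], q[eidx[1]], q[eidx[2]])
        total_area += area
    total_deficit = float(deficit_angles(tri, config).sum())
    return x * (total_area - zeta * total_deficit)


# ---------------------------------------------------------------------------
# State sum
# ---------------------------------------------------------------------------

def _triangle_tables(tri: Triangulation2D, l_amp: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per 3-bit sign pattern of a triangle's edges: (valid flag, area)."""
    valid = np.zeros(8, dtype=bool)
    area = np.zeros(8)
    for bits in range(8):
        q = [1.0 + l_amp * (1 if (bits >> k) & 1 else -1) for k in range(3)]
        try:
            area[bits], _ = triangle_geometry(*q)
            valid[bits] = True
        except ValueError:
            valid[bits] = False
    return valid, area


def z2_regge_partition(tri: Triangulation2D, l_amp: float, x: float,
                       zeta: float, alpha: float = 0.0,
                       cap: int = DEFAULT_EDGE_CAP,
                       return_count: bool = False):
    """Exact state sum Z = Σ_{σ∈{±1}^𝒩} F(q) Π_l q_l^{-α} e^{-A(q)}.

    Enumerates all 2^𝒩 edge-sign configurations in vectorized chunks.  The
    total-deficit part of the action is 2πχ for every valid configuration
    (Gauss–Bonnet), so only the area sums vary between configurations.
    With ``return_count`` also returns the number of valid configurations.
    """
    E = tri.n_edges
    if E > cap:
        raise ValueError(f"{E} edges exceeds the enumeration cap {cap}")
    if x <= 0 or zeta < 0:
        raise ValueError("need x > 0 and zeta >= 0")
    valid_tab, area_tab = _triangle_tables(tri, l_amp)
    tri_edges = np.array(tri.triangle_edges())  # (F, 3)
    chi = tri.euler_characteristic()
    logq_plus = -alpha * math.log1p(l_amp)
    logq_minus = -alpha * math.log1p(-l_amp) if l_amp > 0 else 0.0
    Z = 0.0
    n_valid = 0
    chunk = 1 << 16
    for start in range(0, 1 << E, chunk):
        codes = np.arange(start, min(start + chunk, 1 << E), dtype=np.int64)
        bits = (codes[:, None] >> np.arange(E)) & 1  # (B, E), 1 means σ=+1
        tri_bits = (bits[:, tri_edges[:, 0]]
                    + 2 * bits[:, tri_edges[:, 1]]
                    + 4 * bits[:, tri_edges[:, 2]])  # (B, F) 3-bit patterns
        ok = valid_tab[tri_bits].all(axis=1)
        if not ok.any():
            continue
        areas = area_tab[tri_bits[ok]].sum(axis=1)
        n_plus = bits[ok].sum(axis=1)
        log_measure = n_plus * logq_plus + (E - n_plus) * logq_minus
        action = x * (areas - zeta * 2 * math.pi * chi)
        Z += float(np.exp(log_measure - action).sum())
        n_valid += int(ok.sum())
    if return_count:
        return Z, n_valid
    return Z


def partition_scan(tri: Triangulation2D, l_grid, x: float, zeta: float,
                   alpha: float = 0.0) -> pd.DataFrame:
    """Z and valid-configuration count over a grid of edge amplitudes."""
    rows = []
    for l_amp in l_grid:
        Z, n_valid = z2_regge_partition(tri, l_amp, x, zeta, alpha,
                                        return_count=True)
        rows.append({"l_amp": l_amp, "x": x, "zeta": zeta, "alpha": alpha,
                     "Z": Z, "n_valid_configs": n_valid})
    return pd.DataFrame(rows)
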