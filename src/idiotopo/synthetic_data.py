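"""Seeded generators for every input the toolkit consumes.

No external data is needed anywhere: random coupling models follow the
model's stated sampling rule (Erdős–Rényi support, couplings i.i.d. uniform
on [-1, +1], symmetric, zero diagonal); planted presets provide graphs with
known Betti vectors for the recovery loop; noisy trajectories emulate
measured antibody-concentration time series by adding i.i.d. Gaussian
observation noise to the deterministic 0/1 dynamics; and circle clouds are
the canonical H1 fixture for the persistence pipeline.  Every generator is
a pure function of its configuration — the same seed reproduces identical
output, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .dynamics import simulate
from .network_model import CouplingModel, ImmuneState
from .regge import Triangulation2D, torus16
from .simplicial import BettiVector, SimplicialComplex, betti_numbers, clique_complex
from .tda import DistanceMatrix

PRESETS = ("cycle", "octahedron", "two_components", "torus16")


@dataclass
class GeneratorConfig:
    """Knobs for the random-model generator; the seed fixes every draw."""

    N: int = 8
    edge_prob: float = 0.3
    coupling_dist: str = "uniform_pm1"
    noise_sd: float = 0.05
    seed: int = 0
    preset: str = "none"

    def __post_init__(self) -> None:
        if not 0 <= self.edge_prob <= 1:
            raise ValueError("edge_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.coupling_dist != "uniform_pm1":
            raise ValueError(f"unknown coupling distribution {self.coupling_dist!r}")


def random_coupling_model(cfg: GeneratorConfig, S: float = 0.0) -> CouplingModel:
    """Erdős–Rényi support; J uniform on [-1, 1], symmetrized, zero diagonal."""
    rng = np.random.default_rng(cfg.seed)
    N = cfg.N
    J = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            if rng.random() < cfg.edge_prob:
                J[i, j] = J[j, i] = rng.uniform(-1.0, 1.0)
    return CouplingModel(N=N, S=S, pairwise=J)


def _preset_graph(preset: str) -> tuple[nx.Graph, int]:
    if preset == "cycle":
        return nx.cycle_graph(4), 4
    if preset == "octahedron":
        g = nx.complete_multipartite_graph(2, 2, 2)  # K_{2,2,2}
        return nx.Graph(g), 6
    if preset == "two_components":
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        return g, 6
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def planted_model(preset: str, coupling_value: float = -0.5, S: float = 0.0):
    """Preset fixture with its verified Betti vector.

    Returns (CouplingModel, SimplicialComplex, BettiVector) for the graph
    presets — cycle (1,1), octahedron (1,0,1), two_components (2,0) — and a
    :class:`Triangulation2D` for ``torus16``.  The Betti vector is computed
    (not hard-coded) through exact homology, keeping the preset honest.
    """
    if preset == "torus16":
        return torus16()
    g, N = _preset_graph(preset)
    J = np.zeros((N, N))
    for u, v in g.edges:
        J[u, v] = J[v, u] = coupling_value
    model = CouplingModel(N=N, S=S, pairwise=J)
    cx = clique_complex(g, N=N, max_dim=max(N - 1, 1))
    return model, cx, betti_numbers(cx)


def noisy_trajectories(model: CouplingModel, complex: SimplicialComplex | None,
                       init, steps: int, noise_sd: float = 0.05,
                       seed: int = 0, mode: str = "synchronous") -> np.ndarray:
    """Antibody × timepoint matrix: deterministic dynamics plus i.i.d.
    Gaussian observation noise on every entry."""
    if steps < 3:
        raise ValueError("need at least 3 steps for downstream correlations")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    traj = simulate(model, complex, init, steps, mode=mode)
    X = traj.as_matrix().T.astype(float)  # rows = antibodies
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    return X


def circle_cloud(n_points: int = 40, radius: float = 1.0,
                 jitter_sd: float = 0.0, seed: int = 0) -> DistanceMatrix:
    """Euclidean distances of n points equally spaced on a circle, with
    optional Gaussian coordinate jitter."""
    if n_points < 4:
        raise ValueError("need at least 4 points")
    theta = 2 * np.pi * np.arange(n_points) / n_points
    pts = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
    return DistanceMatrix(squareform(pdist(pts)))


def two_cluster_cloud(n_per_cluster: int = 12, spread: float = 0.5,
                      separation: float = 10.0, seed: int = 0) -> DistanceMatrix:
    """Two dense Gaussian clusters with inter-cluster distance ~separation
    (≫ intra-cluster scale): the canonical (2, 0) fixture."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, spread, size=(n_per_cluster, 2))
    b = rng.normal(0.0, spread, size=(n_per_cluster, 2)) + [separation, 0.0]
    pts = np.vstack([a, b])
    return DistanceMatrix(squareform(pdist(pts)))
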