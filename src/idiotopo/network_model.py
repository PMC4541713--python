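"""Binary idiotypic-network model: states, couplings, mean fields, energy.

The model is an antigen-free idiotypic network in the Hopfield/Parisi
tradition: antibody concentrations are binary, c_i ∈ {0,1}, and each
antibody feels a mean field

    h_i = S + Σ_{k≠i} J_ik c_k                       (linear)

which the multilinear extension generalises by attaching couplings to the
cells (simplices) of the clique complex of the coupling graph:

    h_i = S + Σ_{σ ∋ i} J_σ Π_{j ∈ σ, j≠i} c_j       (multilinear)

A cell σ with n+1 vertices encodes a true (n+1)-body interaction: its
contribution to any h_i vanishes as soon as a single participating antibody
is absent.  The global cost function is E = Σ_i h_i c_i, evaluated on
arbitrary binary configurations (the Heaviside self-consistency condition
defines fixed points of the dynamics, not the ensemble support).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simplicial import SimplicialComplex, clique_complex

__all__ = [
    "ImmuneState", "CouplingModel", "FieldVector", "heaviside",
    "linear_mean_field", "multilinear_mean_field", "energy",
    "read_pairwise_tsv", "write_pairwise_tsv",
    "read_higher_json", "write_higher_json",
    "read_states_csv", "write_states_csv",
]


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImmuneState:
    """Binary vector of antibody concentrations, each entry 0 or 1."""

    c: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(x not in (0, 1) for x in self.c):
            raise ValueError("concentrations must be exactly 0 or 1")

    @classmethod
    def from_array(cls, arr) -> "ImmuneState":
        return cls(c=tuple(int(x) for x in np.asarray(arr).ravel()))

    def as_array(self) -> np.ndarray:
        return np.array(self.c, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.c)


@dataclass(frozen=True)
class FieldVector:
    """Mean-field values h_i; sign decides stimulation vs suppression."""

    h: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.h)):
            raise ValueError("mean-field entries must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(self.h, dtype=float)


@dataclass
class CouplingModel:
    """Threshold S, symmetric pairwise couplings and higher-order couplings.

    ``pairwise`` is an N×N symmetric matrix with zero diagonal; ``higher``
    maps strictly increasing vertex tuples of size >= 3 to coupling values
    J_σ.  ``strict_range`` enforces the sampling interval [-1, +1] as a hard
    constraint (off by default: the interval describes how couplings are
    drawn, not a structural bound).
    """

    N: int
    S: float = 0.0
    pairwise: np.ndarray | None = None
    higher: dict[tuple[int, ...], float] = field(default_factory=dict)
    tau: float = 1.0
    strict_range: bool = False

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.pairwise is None:
            self.pairwise = np.zeros((self.N, self.N))
        self.pairwise = np.asarray(self.pairwise, dtype=float)
        self.validate()

    def validate(self) -> None:
        J = self.pairwise
        if J.shape != (self.N, self.N):
            raise ValueError(f"pairwise must be {self.N}x{self.N}")
        if np.any(np.diag(J) != 0):
            raise ValueError("pairwise diagonal must be zero (J_ii = 0)")
        if not np.allclose(J, J.T):
            raise ValueError("pairwise must be symmetric (J_ik = J_ki)")
        canonical = {}
        for key, val in self.higher.items():
            key = tuple(key)
            if len(key) < 3:
                raise ValueError(f"higher-order key {key} must have size >= 3")
            if list(key) != sorted(set(key)):
                raise ValueError(f"higher-order key {key} must be strictly increasing")
            if key[0] < 0 or key[-1] >= self.N:
                raise ValueError(f"higher-order key {key} outside 0..{self.N - 1}")
            canonical[key] = float(val)
        self.higher = canonical
        if self.strict_range:
            vals = list(self.higher.values()) + list(J.ravel())
            if any(abs(v) > 1 for v in vals):
                raise ValueError("couplings outside [-1, +1] with strict_range on")

    def support_graph(self):
        """Graph 𝒢 generated by the non-zero pairwise couplings."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        ii, kk = np.nonzero(self.pairwise)
        g.add_edges_from((int(i), int(k)) for i, k in zip(ii, kk) if i < k)
        return g

    def complex(self, max_dim: int = 4) -> SimplicialComplex:
        """Clique complex of the support graph (completion of 𝒢)."""
        return clique_complex(self.support_graph(), N=self.N, max_dim=max_dim)


# ---------------------------------------------------------------------------
# Mean fields and energy
# ---------------------------------------------------------------------------

def heaviside(x: float, at_zero: int = 1) -> int:
    """Threshold function Θ: 0 for negative x, 1 for positive x.

    Θ(0) defaults to 1 so that Θ(h) always lands in {0,1} under a
    deterministic update; pass ``at_zero=0`` for the other convention.
    """
    if not np.isfinite(x):
        raise ValueError("heaviside requires finite input")
    if at_zero not in (0, 1):
        raise ValueError("at_zero must be 0 or 1")
    if x < 0:
        return 0
    if x > 0:
        return 1
    return at_zero


def _as_array(state) -> np.ndarray:
    if isinstance(state, ImmuneState):
        return state.as_array()
    arr = np.asarray(state)
    if not np.all((arr == 0) | (arr == 1)):
        raise ValueError("state entries must be 0 or 1")
    return arr.astype(np.int8)


def linear_mean_field(state, model: CouplingModel) -> FieldVector:
    """h_i = S + Σ_{k≠i} J_ik c_k (pairwise couplings only)."""
    c = _as_array(state)
    if len(c) != model.N:
        raise ValueError(f"state length {len(c)} != model N {model.N}")
    h = model.S + model.pairwise @ c.astype(float)
    return FieldVector(h=tuple(h))


def multilinear_mean_field(state, model: CouplingModel,
                           complex: SimplicialComplex) -> FieldVector:
    """Mean field with couplings on the cells of the clique complex.

    Each coupled simplex σ containing i adds J_σ times the product of the
    concentrations of the *other* vertices of σ, so a pairwise-only model
    reduces exactly to the linear mean field.
    """
    c = _as_array(state)
    if len(c) != model.N:
        raise ValueError(f"state length {len(c)} != model N {model.N}")
    h = model.S + model.pairwise @ c.astype(float)
    for key, J in model.higher.items():
        if not complex.has_simplex(key):
            raise ValueError(f"higher-order coupling key {key} is not a simplex "
                             "of the complex")
        vals = c[list(key)]
        total = int(vals.sum())
        if total >= len(key) - 1:
            # product over the other vertices is 1 only if at most the
            # focal vertex itself is absent
            for pos, i in enumerate(key):
                if total - vals[pos] == len(key) - 1:
                    h[i] += J
    return FieldVector(h=tuple(h))


def energy(state, model: CouplingModel, complex: SimplicialComplex | None = None) -> float:
    """Global cost function E = Σ_i h_i(c) c_i on the supplied configuration."""
    if complex is None:
        if model.higher:
            raise ValueError("model has higher-order couplings; pass the complex")
        h = linear_mean_field(state, model).as_array()
    else:
        h = multilinear_mean_field(state, model, complex).as_array()
    c = _as_array(state).astype(float)
    return float(h @ c)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_pairwise_tsv(model: CouplingModel, path: str) -> None:
    """Edge list TSV with header i, j, J (0-based ids, i < j)."""
    ii, kk = np.nonzero(model.pairwise)
    rows = [(int(i), int(k), model.pairwise[i, k])
            for i, k in zip(ii, kk) if i < k]
    pd.DataFrame(rows, columns=["i", "j", "J"]).to_csv(path, sep="\t", index=False)


def read_pairwise_tsv(path: str, N: int, S: float = 0.0, **kwargs) -> CouplingModel:
    df = pd.read_csv(path, sep="\t")
    J = np.zeros((N, N))
    for _, row in df.iterrows():
        i, j = int(row["i"]), int(row["j"])
        if not 0 <= i < j < N:
            raise ValueError(f"bad edge ({i}, {j}) in {path}: need 0 <= i < j < N")
        J[i, j] = J[j, i] = float(row["J"])
    return CouplingModel(N=N, S=S, pairwise=J, **kwargs)


def write_higher_json(higher: dict[tuple[int, ...], float], path: str) -> None:
    payload = [{"simplex": list(k), "J": v} for k, v in sorted(higher.items())]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_higher_json(path: str) -> dict[tuple[int, ...], float]:
    with open(path) as fh:
        payload = json.load(fh)
    return {tuple(entry["simplex"]): float(entry["J"]) for entry in payload}


def write_states_csv(states: list, path: str) -> None:
    arr = np.array([_as_array(s) for s in states], dtype=int)
    pd.DataFrame(arr).to_csv(path, index=False, header=False)


def read_states_csv(path: str) -> list[ImmuneState]:
    arr = pd.read_csv(path, header=None).to_numpy()
    return [ImmuneState.from_array(row) for row in arr]
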