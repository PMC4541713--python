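"""Discrete-time threshold dynamics of the idiotypic network.

The update rule is c_i(t+τ) = Θ[h_i(t)]; the default schedule is
synchronous (all antibodies respond in parallel within one immune-response
time step τ), with an asynchronous index-order sweep provided for
robustness experiments.  ``attractors`` enumerates all 2^N initial states
exactly and reports every cycle with its basin size — feasible because the
dynamics is deterministic, so the state space is a functional graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_model import (CouplingModel, ImmuneState, heaviside,
                            multilinear_mean_field, _as_array)
from .simplicial import SimplicialComplex

MODES = ("synchronous", "asynchronous_sweep")
DEFAULT_ENUMERATION_CAP = 16


@dataclass
class Trajectory:
    """Ordered states visited by the dynamics; one row per time step τ."""

    states: list[ImmuneState]
    mode: str
    tau: float = 1.0

    def as_matrix(self) -> np.ndarray:
        """Time × antibody 0/1 matrix."""
        return np.array([s.as_array() for s in self.states], dtype=np.int8)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.as_matrix()).to_csv(path, index=False, header=False)

    @classmethod
    def from_csv(cls, path: str, mode: str = "synchronous") -> "Trajectory":
        arr = pd.read_csv(path, header=None).to_numpy()
        return cls(states=[ImmuneState.from_array(r) for r in arr], mode=mode)


@dataclass
class AttractorReport:
    """Every attractor (minimal cycle of states) with its basin size."""

    attractors: list[tuple[list[ImmuneState], int]]
    N: int
    mode: str

    def basin_total(self) -> int:
        return sum(size for _, size in self.attractors)

    def cycle_lengths(self) -> list[int]:
        return [len(cycle) for cycle, _ in self.attractors]

    def to_json(self) -> str:
        payload = {
            "N": self.N,
            "mode": self.mode,
            "attractors": [
                {"cycle": [list(s.c) for s in cycle], "basin_size": size}
                for cycle, size in self.attractors
            ],
        }
        return json.dumps(payload, indent=1)


def _field(c: np.ndarray, model: CouplingModel,
           complex: SimplicialComplex | None) -> np.ndarray:
    if complex is None:
        if model.higher:
            raise ValueError("model has higher-order couplings; pass the complex")
        return model.S + model.pairwise @ c.astype(float)
    return multilinear_mean_field(c, model, complex).as_array()


def step(state, model: CouplingModel, complex: SimplicialComplex | None = None,
         mode: str = "synchronous", theta_at_zero: int = 1) -> ImmuneState:
    """One update c_i <- Θ(h_i) under the chosen schedule."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    c = _as_array(state).copy()
    if mode == "synchronous":
        h = _field(c, model, complex)
        new = np.array([heaviside(x, theta_at_zero) for x in h], dtype=np.int8)
        return ImmuneState.from_array(new)
    # asynchronous sweep: vertices in index order, freshest values
    for i in range(model.N):
        h = _field(c, model, complex)
        c[i] = heaviside(h[i], theta_at_zero)
    return ImmuneState.from_array(c)


def simulate(model: CouplingModel, complex: SimplicialComplex | None,
             init, steps: int, mode: str = "synchronous",
             theta_at_zero: int = 1) -> Trajectory:
    """Deterministic trajectory of length steps+1 starting at ``init``."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    state = init if isinstance(init, ImmuneState) else ImmuneState.from_array(init)
    states = [state]
    for _ in range(steps):
        state = step(state, model, complex, mode=mode, theta_at_zero=theta_at_zero)
        states.append(state)
    return Trajectory(states=states, mode=mode, tau=model.tau)


def is_fixed_point(state, model: CouplingModel,
                   complex: SimplicialComplex | None = None,
                   theta_at_zero: int = 1) -> bool:
    """Self-consistency c_i = Θ(h_i(c)) for all i."""
    c = _as_array(state)
    h = _field(c, model, complex)
    return all(int(c[i]) == heaviside(h[i], theta_at_zero) for i in range(len(c)))


def _all_configs(N: int) -> np.ndarray:
    """All 2^N binary configurations; row index is the big-endian bit code."""
    codes = np.arange(2 ** N, dtype=np.int64)
    return ((codes[:, None] >> np.arange(N - 1, -1, -1)) & 1).astype(np.int8)


def _transition_table(model: CouplingModel, complex: SimplicialComplex | None,
                      mode: str, theta_at_zero: int) -> np.ndarray:
    """next-state index for every configuration code."""
    N = model.N
    C = _all_configs(N)
    weights = 1 << np.arange(N - 1, -1, -1, dtype=np.int64)
    if mode == "synchronous" and not model.higher:
        H = model.S + C.astype(float) @ model.pairwise.T
        if theta_at_zero == 1:
            nxt = (H >= 0).astype(np.int64)
        else:
            nxt = (H > 0).astype(np.int64)
        return nxt @ weights
    out = np.empty(2 ** N, dtype=np.int64)
    for code in range(2 ** N):
        nxt = step(C[code], model, complex, mode=mode,
                   theta_at_zero=theta_at_zero).as_array()
        out[code] = int(nxt.astype(np.int64) @ weights)
    return out


def attractors(model: CouplingModel, complex: SimplicialComplex | None = None,
               mode: str = "synchronous", theta_at_zero: int = 1,
               cap: int = DEFAULT_ENUMERATION_CAP) -> AttractorReport:
    """Exhaustive attractor analysis over all 2^N initial states.

    Cycles are detected by walking the deterministic transition table and
    hashing visited states; basin sizes count every configuration flowing
    into each cycle (cycle states included), so they sum to 2^N.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    N = model.N
    if N > cap:
        raise ValueError(f"N={N} exceeds the enumeration cap {cap}; "
                         "sample trajectories instead of exhaustive analysis")
    table = _transition_table(model, complex, mode, theta_at_zero)
    n = 2 ** N
    cycle_id = np.full(n, -1, dtype=np.int64)
    cycles: list[list[int]] = []
    for start in range(n):
        if cycle_id[start] >= 0:
            continue
        path = []
        pos: dict[int, int] = {}
        node = start
        while cycle_id[node] < 0 and node not in pos:
            pos[node] = len(path)
            path.append(node)
            node = int(table[node])
        if cycle_id[node] >= 0:
            cid = int(cycle_id[node])
        else:
            cid = len(cycles)
            k = pos[node]
            cycles.append(path[k:])
        for p in path:
            cycle_id[p] = cid
    basin = np.bincount(cycle_id, minlength=len(cycles))
    C = _all_configs(N)
    attr = []
    for cid, cyc in enumerate(cycles):
        # rotate so the cycle starts at its smallest configuration code
        k = cyc.index(min(cyc))
        cyc = cyc[k:] + cyc[:k]
        states = [ImmuneState.from_array(C[code]) for code in cyc]
        attr.append((states, int(basin[cid])))
    attr.sort(key=lambda t: t[0][0].c)
    return AttractorReport(attractors=attr, N=N, mode=mode)
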