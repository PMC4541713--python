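"""Coupling inference from target Betti numbers and the S[B] adaptation loop.

The inverse problem — which coupling support graph gives a clique complex
with prescribed Betti numbers — is under-determined, so it is solved as a
seeded stochastic search: simulated annealing over single-edge toggles with
the L1 Betti distance as cost, and every returned witness re-verified
through exact simplicial homology before being accepted.

Coupling *values* follow the geometric rule of the model: a cell's coupling
is a negative linear combination of its n-volume and of the volume of its
(n-2)-boundary weighted by a curvature factor, so larger cells carry more
negative (more strongly suppressive) couplings.

The S[B] machinery wraps the network dynamics (the behavioural machine B)
in a structural controller S whose states are topological contexts: each S
state is labelled by a Betti-vector constraint, and the observation function
O maps every B state to the Betti vector of the current model complex.
Adaptation is triggered exactly when the data's Betti numbers disagree with
the model's; a new support is inferred, new couplings assigned, and a new
context appended (previous contexts are never deleted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .network_model import CouplingModel, ImmuneState
from .simplicial import BettiVector, SimplicialComplex, betti_numbers, clique_complex
from .tda import compare_betti

__all__ = [
    "SBSystem", "SearchFailure", "infer_coupling_support",
    "assign_coupling_values", "model_from_complex", "build_sb_system",
    "sb_adapt", "check_sb",
]


# ---------------------------------------------------------------------------
# Support inference
# ---------------------------------------------------------------------------

class SearchFailure(RuntimeError):
    """Annealing exhausted its budget without hitting the target; carries
    the best graph found and its Betti distance."""

    def __init__(self, message: str, best_graph: nx.Graph, best_betti: BettiVector,
                 best_distance: int, evaluations: int):
        super().__init__(message)
        self.best_graph = best_graph
        self.best_betti = best_betti
        self.best_distance = best_distance
        self.evaluations = evaluations


def _full_betti(g: nx.Graph, N: int) -> BettiVector:
    """Betti vector of the full (uncapped) clique complex of g."""
    cx = clique_complex(g, N=N, max_dim=max(N - 1, 1))
    return betti_numbers(cx)


def _seed_graph(rng: np.random.Generator, N: int, target: BettiVector) -> nx.Graph:
    """Random starting support biased toward the target's component count."""
    g = nx.Graph()
    g.add_nodes_from(range(N))
    p = rng.uniform(0.2, 0.6)
    for i in range(N):
        for j in range(i + 1, N):
            if rng.random() < p:
                g.add_edge(i, j)
    return g


def infer_coupling_support(N: int, target: BettiVector, budget: int = 1000,
                           seed: int = 0) -> nx.Graph:
    """Search for a graph whose clique complex has exactly the target Betti
    vector, by simulated annealing over edge toggles.

    The budget counts cost evaluations; the search restarts from a fresh
    random graph whenever a restart's annealing schedule is exhausted.
    Every candidate success is re-verified through exact homology before
    being returned; exhaustion raises :class:`SearchFailure` with the best
    graph found.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if len(target) == 0 or target[0] < 1:
        raise ValueError("target b_0 must be >= 1 (a non-empty complex)")
    if target[0] > N:
        raise ValueError(f"target b_0={target[0]} exceeds N={N}: unsatisfiable")
    rng = np.random.default_rng(seed)
    edges = [(i, j) for i in range(N) for j in range(i + 1, N)]
    evaluations = 0
    best: tuple[int, nx.Graph, BettiVector] | None = None
    restart_len = max(50, 4 * len(edges))
    while evaluations < budget:
        g = _seed_graph(rng, N, target)
        bv = _full_betti(g, N)
        cost, _ = compare_betti(bv, target)
        evaluations += 1
        if best is None or cost < best[0]:
            best = (cost, g.copy(), bv)
        if cost == 0:
            break
        t0, t1 = 2.0, 0.05
        steps = min(restart_len, budget - evaluations)
        for k in range(steps):
            T = t0 * (t1 / t0) ** (k / max(steps - 1, 1))
            i, j = edges[rng.integers(len(edges))]
            if g.has_edge(i, j):
                g.remove_edge(i, j)
            else:
                g.add_edge(i, j)
            new_bv = _full_betti(g, N)
            new_cost, _ = compare_betti(new_bv, target)
            evaluations += 1
            if new_cost <= cost or rng.random() < math.exp((cost - new_cost) / T):
                cost, bv = new_cost, new_bv
            else:  # revert the toggle
                if g.has_edge(i, j):
                    g.remove_edge(i, j)
                else:
                    g.add_edge(i, j)
            if cost < best[0]:
                best = (cost, g.copy(), bv)
            if cost == 0:
                break
        if best[0] == 0:
            break
    cost, g, bv = best
    if cost != 0:
        raise SearchFailure(
            f"no graph matching Betti {tuple(target.b)} found in {evaluations} "
            f"evaluations (best distance {cost})", g, bv, cost, evaluations)
    # self-auditing contract: verify the witness through exact homology
    verified = _full_betti(g, N)
    dist, ok = compare_betti(verified, target)
    assert ok, "internal error: witness failed re-verification"
    return g


# ---------------------------------------------------------------------------
# Coupling values from cell geometry
# ---------------------------------------------------------------------------

def regular_simplex_volume(n: int) -> float:
    """n-volume of the regular n-simplex with unit edge length:
    sqrt(n+1) / (n! sqrt(2^n)).  V_0 = 1, V_1 = 1, V_2 = sqrt(3)/4."""
    if n < 0:
        raise ValueError("dimension must be >= 0")
    return math.sqrt(n + 1) / (math.factorial(n) * math.sqrt(2 ** n))


def assign_coupling_values(complex: SimplicialComplex, a: float = 1.0,
                           b: float = 1.0,
                           curvature_weights: dict[int, float] | None = None
                           ) -> dict[tuple[int, ...], float]:
    """J_σ = -(a V_n + b κ_n W_n) for every simplex σ of dimension n >= 1.

    V_n is the unit-edge regular n-simplex volume, W_n the total volume of
    the (n-2)-faces of σ (zero for n < 2), and κ_n a per-dimension curvature
    weight (1 by default).  All couplings are <= 0 and more negative for
    larger cells; a = b = 0 switches the interaction off entirely.
    """
    if a < 0 or b < 0:
        raise ValueError("a and b must be >= 0")
    curvature_weights = curvature_weights or {}
    out: dict[tuple[int, ...], float] = {}
    for n in range(1, complex.max_dim + 1):
        V = regular_simplex_volume(n)
        if n >= 2:
            W = math.comb(n + 1, n - 1) * regular_simplex_volume(n - 2)
        else:
            W = 0.0
        kappa = curvature_weights.get(n, 1.0)
        J = -(a * V + b * kappa * W)
        for s in complex.simplices.get(n, []):
            out[s] = J
    return out


def model_from_complex(complex: SimplicialComplex, S: float = 0.0,
                       a: float = 1.0, b: float = 1.0,
                       curvature_weights: dict[int, float] | None = None
                       ) -> CouplingModel:
    """CouplingModel whose support is the 1-skeleton and whose couplings are
    the geometric values of :func:`assign_coupling_values`."""
    values = assign_coupling_values(complex, a=a, b=b,
                                    curvature_weights=curvature_weights)
    J = np.zeros((complex.N, complex.N))
    higher = {}
    for key, val in values.items():
        if len(key) == 2:
            J[key[0], key[1]] = J[key[1], key[0]] = val
        else:
            higher[key] = val
    return CouplingModel(N=complex.N, S=S, pairwise=J, higher=higher)


# ---------------------------------------------------------------------------
# S[B] systems
# ---------------------------------------------------------------------------

@dataclass
class SBSystem:
    """Behavioural machine B under a structural controller S.

    B = (Q, q0, ->B): Q as state tuples, q0 initial, transitions from the
    network dynamics.  S = (R, r0, O, ->S, L): R context names, O maps every
    B state to a Betti vector (the model's topological context), ->S the
    adaptation history, L labels each context with its Betti constraint.
    """

    Q: list[tuple[int, ...]]
    q0: tuple[int, ...]
    b_transitions: dict[tuple[int, ...], tuple[int, ...]]
    R: list[str]
    r0: str
    observation: dict[tuple[int, ...], tuple[int, ...]]
    s_transitions: list[tuple[str, str]] = field(default_factory=list)
    constraints: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def current_context(self) -> str:
        return self.R[-1]


def _satisfies(observed: tuple[int, ...], constraint: tuple[int, ...]) -> bool:
    L = max(len(observed), len(constraint))
    pad = lambda t: tuple(t) + (0,) * (L - len(t))
    return pad(observed) == pad(constraint)


def check_sb(system: SBSystem) -> tuple[bool, list[str]]:
    """Validate the S[B] invariants; returns (ok, itemized violations)."""
    violations = []
    qset = set(system.Q)
    if system.q0 not in qset:
        violations.append(f"initial B state {system.q0} not in Q")
    for q in system.Q:
        if q not in system.observation:
            violations.append(f"observation undefined on state {q}")
    for q, q2 in system.b_transitions.items():
        if q not in qset or q2 not in qset:
            violations.append(f"transition {q} -> {q2} leaves Q")
    for r in system.R:
        if r not in system.constraints:
            violations.append(f"no constraint attached to S state {r}")
    if system.r0 not in system.R:
        violations.append(f"initial S state {system.r0} not in R")
    if (system.q0 in system.observation and system.r0 in system.constraints
            and not _satisfies(system.observation[system.q0],
                               system.constraints[system.r0])):
        violations.append("initial-constraint violation: q0 does not satisfy L(r0)")
    return (not violations), violations


def build_sb_system(model: CouplingModel, complex: SimplicialComplex,
                    init: ImmuneState | None = None,
                    context_name: str = "r0") -> SBSystem:
    """S[B] system for a model: Q is the full binary state space (small N),
    B transitions come from the synchronous dynamics, and every B state
    observes the Betti vector of the model's complex as its context."""
    from .dynamics import step

    N = model.N
    if N > 16:
        raise ValueError("state space too large to build Q exhaustively")
    bv = tuple(betti_numbers(complex).b)
    Q = []
    trans = {}
    for code in range(2 ** N):
        c = tuple((code >> (N - 1 - i)) & 1 for i in range(N))
        Q.append(c)
        trans[c] = tuple(step(np.array(c), model, complex).c)
    q0 = tuple(init.c) if init is not None else Q[0]
    return SBSystem(Q=Q, q0=q0, b_transitions=trans, R=[context_name],
                    r0=context_name, observation={q: bv for q in Q},
                    s_transitions=[], constraints={context_name: bv})


def sb_adapt(system: SBSystem, model: CouplingModel, complex: SimplicialComplex,
             data_betti: BettiVector, seed: int = 0, budget: int = 1000,
             a: float = 1.0, b: float = 1.0
             ) -> tuple[SBSystem, CouplingModel, SimplicialComplex]:
    """One S[B] adaptation phase driven by the data's Betti numbers.

    If the model complex already has the data's Betti vector there is no new
    knowledge and the inputs are returned unchanged.  Otherwise a new
    coupling support is inferred, geometric coupling values assigned, and a
    new topological context appended to S; all S[B] invariants are
    re-established on the returned system.
    """
    model_bv = betti_numbers(complex)
    _, match = compare_betti(model_bv, data_betti)
    if match:
        return system, model, complex
    g = infer_coupling_support(model.N, data_betti, budget=budget, seed=seed)
    new_complex = clique_complex(g, N=model.N, max_dim=max(model.N - 1, 1))
    new_model = model_from_complex(new_complex, S=model.S, a=a, b=b)
    new_bv = tuple(betti_numbers(new_complex).b)
    context = f"r{len(system.R)}"
    from .dynamics import step

    new_trans = {q: tuple(step(np.array(q), new_model, new_complex).c)
                 for q in system.Q}
    new_system = replace(
        system,
        b_transitions=new_trans,
        R=system.R + [context],
        r0=context,  # the system restarts in the new topological context
        observation={q: new_bv for q in system.Q},
        s_transitions=system.s_transitions + [(system.current_context(), context)],
        constraints={**system.constraints, context: new_bv},
    )
    ok, violations = check_sb(new_system)
    if not ok:
        raise RuntimeError(f"adaptation produced an invalid S[B] system: {violations}")
    return new_system, new_model, new_complex
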