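# Methods

## The model

`idiotopo` works with an antigen-free idiotypic network of N antibodies
with binary concentrations c_i ∈ {0,1}.  The linear mean field is
h_i = S + Σ_{k≠i} J_ik c_k with symmetric couplings (J_ik = J_ki, J_ii = 0)
and threshold S; the sign of J_ik decides stimulation vs suppression and
|J_ik| its strength.  Couplings are *sampled* from [−1, +1]; the interval is
treated as the sampling convention, not a structural bound, so models with
larger couplings are accepted unless `strict_range` is set.

The multilinear extension attaches couplings to cells of the clique complex
𝒞 of the coupling graph 𝒢: an (n+1)-vertex cell σ with coupling J_σ
contributes J_σ Π_{j∈σ, j≠i} c_j to h_i for each i ∈ σ.  The product runs
over the *other* vertices of the cell, which makes the pairwise case reduce
exactly to the linear field.  A cell's contribution vanishes as soon as one
participant is inactive — the defining property of an irreducible n-body
interaction.

The global cost function is E(c) = Σ_i h_i(c) c_i, evaluated on arbitrary
binary configurations.  The threshold self-consistency c_i = Θ(h_i) defines
the *fixed points of the dynamics*, not the support of the ensemble: the
partition function deliberately sums over all 2^N valuations.  Concentrations
are kept strictly binary throughout; no continuous relaxation is attempted.

Θ(0) := 1 by default (so Θ(h) always lands in {0,1} under a deterministic
update); the other convention is available via `at_zero=0`.

## Dynamics

The update c_i(t+τ) = Θ[h_i(t)] is applied synchronously by default (the
parallel reading of the iterated cascade); an asynchronous index-order sweep
is provided for robustness experiments, and every output records which
schedule produced it.  Attractor analysis enumerates all 2^N initial
states (cap N ≤ 16, configurable), detects cycles by hashing visited
states, and reports basin sizes that provably sum to 2^N.  The classical
result that synchronous symmetric pairwise threshold networks only admit
cycles of length ≤ 2 is *verified* empirically in the suite for N ≤ 10, not
assumed, and is not asserted for multilinear models.

## Statistical mechanics

Z(x) = Σ_c e^{−xE(c)} is computed by exact enumeration (cap N ≤ 20).
Energies over all configurations are evaluated vectorised from the identity
E(c) = S Σ c_i + Σ_{i<k} 2 J_ik c_i c_k + Σ_σ |σ| J_σ Π_{j∈σ} c_j.
Weights are accumulated with a max-shift (log-sum-exp style), which keeps
x = 0 exactly at 2^N and avoids overflow at large x·|E|; Z may overflow to
inf for extreme parameters while log Z stays finite and is reported
alongside.  Correlation functions Γ_k are ratio estimators under the same
shift and so are exact.  One prose convention in the source material counts
2^{N−1} configurations (identifying c with 1−c); the ensemble here sums
over all 2^N valuations, and `identify_global_flip=True` folds the sum to
the 2^{N−1} equivalence classes for exploratory use.  The sweep's crossover
flag marks the grid point of steepest |dm/dx| by finite differences — a
candidate symmetry-breaking scale, not a phase-transition claim (these
systems are finite).

The relationship between Z(x) and the Betti generating function (Poincaré
polynomial) is reported side by side — both objects are computed — without
enforcing an identity, since no explicit variable mapping between the
ensemble parameter and the polynomial variable is available.

## Homology

The clique complex is built by enumerating cliques (networkx) up to
`max_dim` (default 4; capping is logged because it truncates homology
above the cap).  Simplices are stored sorted and in lexicographic order, so
boundary matrices are reproducible bit-for-bit.  Betti numbers come from
b_n = dim ker ∂_n − rank ∂_{n+1}; over GF(2) ranks use bitset Gaussian
elimination (fast, and the natural field for a Z2-valued model), over ℚ the
signed boundary operator with exact sympy ranks (torsion-aware, slower).
The Euler–Poincaré identity Σ(−1)^n b_n = Σ(−1)^n #C_n holds for any finite
chain complex, including a truncated one, and is used as a blanket
correctness check on random complexes.

## Persistent homology

No TDA library is used: Vietoris–Rips persistence is implemented in-package
as the standard boundary-matrix reduction over GF(2), dimension by
dimension, with columns in filtration order held as integer bitsets.  The
filtration value of a simplex is its largest pairwise distance; the complex
is built one dimension above the requested homological dimension so that
deaths are observed.  The implementation is exact and deterministic, sized
for the toolkit's regime (tens of points, H0–H2); it is cross-checked in
the suite against exact simplicial homology of thresholded clique
complexes.  Zero-persistence pairs are kept, so the count of dimension-0
bars at scale 0 equals the number of points.

Data enter as antibody × timepoint matrices; the proximity notion is the
correlation distance d_ij = 1 − ρ_ij (anti-correlated antibodies maximally
far), with 1 − |ρ| available by flag; zero-variance rows get ρ := 0 with a
warning rather than an error.  Points are antibodies (the antibody-as-point
convention); the dual, sample-space analysis is left open.

The empirical Betti vector is read at the midpoint of the longest scale
interval on which the whole Betti vector is constant (plateau rule), with
adjacent equal-valued intervals merged and ties resolved to the earliest
interval; the scan stops at the largest finite diagram value.  The plateau
rule was preferred over total-persistence maximisation for
interpretability; the full diagram is always available for the latter.
Model and data Betti vectors are compared by L1 distance after zero-padding.

## Inverse problem and S[B] adaptation

Finding a coupling support whose clique complex has prescribed Betti
numbers is under-determined, so it is solved as seeded simulated annealing
over single-edge toggles: cost = L1 Betti distance, geometric temperature
schedule (2.0 → 0.05) per restart, random-graph restarts until the
evaluation budget is exhausted, and every success re-verified through exact
homology before being returned (self-auditing).  Budget exhaustion raises a
failure carrying the best graph, its Betti vector and the evaluation count —
failure is reported, never papered over.  The returned graph is *a*
witness, not *the* answer; uniqueness is not claimed.

Coupling values follow the geometric rule J_σ = −(a V_n + b κ_n W_n): V_n
is the unit-edge regular n-simplex volume (√(n+1)/(n!·√2ⁿ)), W_n the total
volume of the (n−2)-faces of σ (zero for n < 2, with V_0 := 1 for
vertices), and κ_n a per-dimension curvature weight defaulting to 1, since
no curvature formula for abstract cells is available; per-dimension weights
are accepted via configuration.  Both coefficients are ≥ 0, so all
couplings are ≤ 0 and larger cells are more suppressive.

An S[B] system wraps the dynamics (machine B: states Q, initial q0,
transition relation) in a structural controller S whose states are
topological contexts labelled by Betti-vector constraints; the observation
function maps every B state to the Betti vector of the current model
complex.  Adaptation triggers exactly when data and model Betti vectors
disagree: a new support is inferred, values assigned, the new context
appended (contexts are never deleted), and the active initial context moved
to the new one so that all invariants — observation total on Q, q0
satisfying the initial constraint — hold on the returned system;
`check_sb` itemises any violation.  Transition invariants constraining the
adaptation path are exposed as structure (the S-transition list), not as
implemented logic.

## Z2 Regge toy

The 2-D toy restricts squared edge lengths of a closed triangulated
surface to q_ℓ = 1 + 𝔩σ_ℓ, σ_ℓ = ±1, 0 ≤ 𝔩 < 1 (so q > 0).  Triangle areas
come from Heron's formula and angles from the law of cosines; configurations
violating a strict triangle inequality have F(q) = 0 and are excluded.
Curvature is the vertex deficit 𝔡(v) = 2π − Σ incident angles, and the
action is A = x(Σ areas − ζ Σ_v 𝔡(v)·V⁰) with the point-volume convention
V⁰ := 1.  Dimension 2 is the minimal setting where the volume+curvature
action is fully exercisable and independently checkable: for any valid
configuration the total deficit equals 2πχ (Gauss–Bonnet), which the state
sum exploits (only areas vary between configurations) and the test suite
verifies against direct angle sums on the tetrahedron, octahedron, and an
8-vertex/16-triangle cyclic torus (triangles {i,i+1,i+3}, {i,i+2,i+3}
mod 8).  The continuum measure dq/q^α becomes the discrete weight q_ℓ^{−α}
per edge.  Enumeration over 2^𝒩 sign vectors (cap 𝒩 ≤ 24) is vectorised in
chunks via 8-entry per-triangle lookup tables.  The σ_ℓ = 2c_ℓ − 1
conversion between edge signs and binary concentrations is provided as a
helper; a full coupling ↔ geometry dictionary is intentionally left open.

## Synthetic data

Random models use an Erdős–Rényi support (default edge probability 0.3 on
N = 8) with couplings i.i.d. uniform on [−1, +1], the model's stated
sampling rule.  Trajectory "measurements" add i.i.d. Gaussian observation
noise (default sd 0.05) to the deterministic 0/1 dynamics — a deliberately
minimal noise model; real concentration data would have temporal
autocorrelation, multiplicative noise and missing values, none of which is
emulated, so passing tests certify the pipeline's correctness, not its
robustness on laboratory data.  Planted presets (4-cycle, octahedron
≅ K_{2,2,2}, two disjoint triangles, the 16-triangle torus) have their
Betti vectors recomputed through exact homology at construction rather than
hard-coded.  Every generator is a pure function of its seed.

## Problem sizes and limitations

All engines are exact and enumerative, so sizes are deliberately small:
ensembles to N = 20 (tests use N ≤ 12), attractors to N = 16 (tests ≤ 10),
Regge edge counts to 24 (state-sum tests use the 6-edge tetrahedron; the
24-edge torus is enumerable but slow and is exercised via deficit checks),
persistence at tens of points and H0–H2.  The annealing search is practical
for N up to ~10 vertices; beyond that each homology evaluation dominates.
Monte-Carlo sampling, continuous concentrations, antigen-driven dynamics
and thermal update rules are out of scope.
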