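# Methods

## Model class

A model is a finite set of N named nodes (proteins, complexes, composite
signals). Each non-input node `i` carries a Boolean update rule in
sum-of-product form: an OR of clauses, each clause an AND of signed
literals over the influencing set `R_i`. Input nodes are exactly the nodes
with no rule; their values represent experimental conditions (receptor
engagement, co-stimulation) and are held fixed. Rules are canonicalized on
construction — literals and clauses sorted, duplicates collapsed,
contradictory clauses (a regulator with both signs in one clause) rejected
— so equal rules serialize identically and round-trips are stable. General
and/or/not expressions (parenthesized text, SBML-qual MathML) are
normalized to SOP by negation-normal form plus distribution; conjuncts that
become identically false are dropped, and a rule whose every clause drops
is rejected rather than silently stored as constant false.

Clause structure is *not* minimized (no absorption): `A | A & B` keeps
both clauses because the literals define the influencing set and hence the
interaction graph. This mirrors how curated models encode evidence — each
clause is one documented mechanism.

## Interaction graph, SCCs and feedback loops

The interaction graph has one signed edge per (regulator, target) literal,
AND structure discarded; multiple occurrences collapse to one edge per
sign, and a regulator used with both signs yields a dual edge. Strongly
connected components come from networkx (Tarjan); the largest non-trivial
SCC is reported with its induced link count as the model's cross-talk core.

Feedback loops are elementary directed cycles, enumerated sign-blind with
Johnson's algorithm (networkx `simple_cycles`) after peeling nodes of
in-degree 0 or out-degree 0. Peeling is iterative by default — removing an
output can expose a new output — with a single-pass mode behind a flag for
comparison, since the two choices can differ on which nodes survive (the
cycle set itself is unaffected; trimming only shrinks the search). Loops
are rotation-canonical (anchored at their lexicographically smallest node)
and sorted, so outputs are deterministic. A configurable cap (default 10⁶
cycles) guards against dense graphs whose cycle count explodes
combinatorially. Each loop can be annotated with its sign parity (product
of edge signs); parity never affects counts.

## Continuous dynamics

The discrete rule `B_i` is interpolated multilinearly over the unit cube
(BooleCube):

    B̄ᴵ(x̄) = Σ_{corners c} B_i(c) · Π_j (x̄_j if c_j else 1 − x̄_j)

implemented as successive one-variable folds of the rule's truth table,
which is algebraically identical to the corner sum but costs O(2^m) rather
than O(m·2^m) per evaluation and vectorizes over batches of states. Each
regulator coordinate is passed through a Hill sigmoid
`f(x) = xⁿ/(xⁿ + kⁿ)` (HillCube); dividing by `f(1)` makes the composite
agree exactly with `B_i` on every binary corner (normalized HillCube),
which is the variant used everywhere downstream. The ODE system is

    ẋ_i = (B̄ᴴⁿ_i(x̄_{R_i}) − x_i)/τ_i

with zero derivative for inputs and clamped nodes. Because `B̄ᴴⁿ ∈ [0,1]`,
the vector field points inward on the boundary of the unit cube, so the
exact flow never leaves it.

Parameters: Hill exponent `n` (cooperativity), threshold `k`
(half-activation), life time `τ`; defaults `n = 3`, `k = 0.5`, `τ = 1`.
Overrides resolve per (influenced, influencing) edge, then node-level
(source `"*"`), then defaults, because tuned parameter sets mix
edge-specific rows with all-regulator rows. Override records apply in file
order with later-wins semantics and a warning on duplicate keys; the
packaged `tcell_params.yaml` transcribes a published tuned set that
contains such duplicates verbatim.

Integration uses adaptive RK45 (scipy `solve_ivp`) with `rtol = 1e-7`,
`atol = 1e-9`, sampled on a dense grid (default spacing 0.25 time units)
for attractor detection. These tolerances keep the dense-output
interpolant within 1e-6 of the unit cube, which the trajectory contract
requires; overshoot below that bound is clipped, larger overshoot is an
error. The system is non-stiff at default parameters. The default horizon
of 200 time units gives a comfortable margin over the ~40 units the
packaged fixture and comparable models need to settle.

The synchronous discrete mode (simultaneous update of all nodes, stop at
the first revisited state) is retained for structural reasoning — e.g. the
two-node negative loop `A = !B, B = A` has the classic period-4 orbit —
but all screen results use the continuous mode.

## Attractor detection and binarization

Detection works on the post-transient part of a trajectory (default: the
last half). A fixed point is called when the finite-difference derivative
over the trailing tenth stays below 1e-4 (max-norm). Otherwise a candidate
period comes from the summed autocorrelation of the mean-centered tail
(first local peak above 0.2, parabolic sub-grid refinement), and is then
refined by minimizing the max-norm distance between the tail and its
period-shifted copy, evaluated on a cubic-spline interpolant so that
periods incommensurate with the sampling grid are handled exactly. The
cycle is accepted when that recurrence distance falls below 1e-3. If
neither criterion fires the caller gets an explicit not-settled error and
should extend the horizon; nothing is guessed.

Binary profiles use max-over-attractor with threshold 0.5: an oscillating
node that swings through high values is biologically "on" (active kinases
pulse). Mean-over-cycle is available behind a flag; for fixed points the
two coincide. Attractor comparison is the element-wise XOR of binary
profiles; the impairment call for a perturbation is "some TF endpoint
active in the wild type is inactive here". The NF-κB endpoint is the
nuclear-competent NFKB1 node; endpoints are configurable.

## Perturbation screens

A perturbation converts one node into an input clamped at 0 (loss of
function) or 1 (constitutive activity) for the entire simulation; clamped
nodes have exactly zero derivative, so their trajectory is constant to the
last bit. All conditions start from the same resting initial state —
non-input nodes at 0, inputs per the signal configuration — the natural
choice for an activation study and exposed as an argument. Clamping a node
that is configured as a signal is refused to keep the two mechanisms
distinct. Screens isolate per-condition failures into their result row,
keep spec order, and put the wild type first in the exported matrix. The
dysregulation table encodes a TF endpoint that differs from wild type as 0
and an unaffected one as 1 by default; the encoding is an argument, since
published effect tables use both conventions and are not always internally
consistent.

## Synthetic models

The generator wires non-input nodes in a topological order with regulators
drawn from strictly earlier nodes, which guarantees by induction that every
non-input node is reachable from some input; `cycle_enrichment` then adds,
per node with that probability, one extra OR clause reading a *later*
non-input node, creating feedback confined to the core (inputs never join
loops, matching how input receptors sit outside signaling feedback).
Defaults (30 nodes, 6 inputs, ≤2 clauses of ≤2 literals, 20% inhibiting
edges, enrichment 0.3) give mid-sized, mostly-activating networks of the
general shape curated signaling models have — a ~20% input fraction and a
loop-bearing core — while staying cheap to enumerate. All randomness flows
from one integer seed; identical seeds give byte-identical serializations.

The toy fixture is hand-written, not generated, so its behaviors are
provable by construction. Its oscillator is a five-node ring with a single
inhibition (DAG→RAS→RAF1→MAPK1→DGK⊣DAG): for a ring of length L with
sigmoid slope `s` at the fixed point, the Hopf/secant condition for
instability is `s^L > sec(π/L)^L`. At the default steepness the per-stage
slope is ≈ 1.76, so a two-node pair (threshold → ∞) and a three-ring
(threshold 8 > 1.76³ ≈ 5.5) are stable spirals, while the five-ring
(1.76⁵ ≈ 17 ≫ sec(π/5)⁵ ≈ 2.9) oscillates robustly — the reason the
fixture's negative feedback spans five nodes. The NF-κB-like endpoint
reads `ITK & LAT & ZAP70`, i.e. both signal arms plus the hub, which
yields the three by-construction screen behaviors: both signals → all
endpoints active; either signal alone → AP1- and NFAT-like endpoints
active, NF-κB-like silent; LAT knockout → everything silent. Clamping
PI3K to 1 with co-stimulation already on reproduces the wild type exactly,
a built-in neutral (overexpression) control.

## What the synthetic conditions do and do not show

The generator and fixture exercise every pipeline stage — parsing,
structure, dynamics, attractor calls, screens — under known ground truth,
and the property suite checks the numerical core against independent
oracles (corner sums, brute-force cycle search, reachability closure,
closed-form ODE solutions). Passing these shows the machinery is correct,
not that any particular curated model is right: real signaling models have
heavier-tailed degree distributions, far denser loop cores (hundreds of
FBLs), and hand-tuned parameters, and their biological conclusions depend
on curation quality that no synthetic test can certify. When an externally
curated SBML-qual model is supplied, the same entry points run unchanged.

## Numerical choices and limitations

* Truth tables are cached per rule; rules with more than ~20 regulators
  would exhaust memory (curated models stay far below this).
* Attractor detection assumes the trajectory has actually entered its
  attractor; quasi-periodic or chaotic behavior (not observed in this
  model class at default parameters) would surface as not-settled.
* Period estimates are resolution-limited by the autocorrelation peak
  width; the spline-refined recurrence brings them well under 2% error on
  synthetic signals.
* No asynchronous or stochastic updating, no multivalued logic, no
  parameter fitting; partial knockdowns (fractional clamps) and double
  perturbations are out of scope.
* `fbl_length_summary` reports the mean to one decimal and the standard
  midpoint median, matching how such tables are usually published.
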