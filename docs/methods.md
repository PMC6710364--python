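# Methods

This note documents the models implemented in `boolfuzz`, the
parameter conventions, the numerical choices, and the limits of what
the bundled fixtures and tests can show.

## Discrete model

Nodes are binary; every non-input node carries one logical rule over
AND/OR/NOT, and all nodes update simultaneously (synchronous scheme —
asynchronous and mixed-timescale updating are out of scope). Input
nodes (cytokines, ligands) carry no rule: they are clamped per
scenario, reflecting the convention that microenvironmental cues are
either absent or present.

Attractor search enumerates, per input configuration, all Ω = 2^(free
nodes) initial states. The successor function is computed once,
vectorized over the whole state space, and each state is walked to its
attractor with memoization, so total work is O(Ω). Basins therefore
partition the state space exactly and the expression probabilities
p = ω/Ω sum to 1 within each configuration. Reported probabilities
are per input configuration; the census view additionally merges
attractors whose free-node profiles coincide across configurations
(an attractor indifferent to an input would otherwise be counted once
per input value). Enumeration refuses state spaces above 2^22 states
and directs the user to model reduction instead.

Cycles are canonicalized by rotating to the lexicographically
smallest member state, making attractor sets independent of
enumeration order. Perturbations follow the usual conventions:
knockout clamps a node's rule to 0, overexpression to 1, and a pulse
forces a value for a fixed number of steps during trajectory
simulation only.

## Fuzzy-logic continuous transform

Each rule is translated connective-by-connective into a proposition
w_k on [0, 1]. Two schemes are provided: Zadeh (min/max/1−p) and
probabilistic (q·p, q+p−q·p, 1−p). The probabilistic scheme is the
default because it yields continuously differentiable right-hand
sides, appropriate for an ODE; both schemes reduce to the Boolean
truth tables at binary arguments, which is the property the
correspondence results rest on. Expressions are flattened before
translation so the compiled function is deterministic in the rule's
written form.

The membership function defaults to the logistic
μ[w] = 1/(1+exp(−β(w−w_thr))). β (dimensionless) sets the steepness
of the false→true transition: β ≈ 3 is a soft, graded response, β = 60
is effectively a step at vertex arguments, and β = 200 is used for
"discrete-limit" checks because the logistic is then within 1e−12 of
the step function at any binary vertex. w_thr defaults to 1/2, the
unique solution of w = 1 − w — the natural boundary between falsity
and truth — and may be overridden per node (kept inside (0, 1)). The
Hill form x^β/(x_thr^β+x^β) is the same sigmoid under w = ln x and is
verified to agree with the logistic to ≤ 1e−12 over six decades.

The dynamics dq_k/dt = μ[w_k(q)] − α_k q_k uses per-node decay rates
α_k (1/time), default 1. α_k encodes the timescale τ_k = 1/α_k of the
biochemical event the node represents; slow transcription is modeled
with α < 1 (e.g. 0.2), fast signaling with α ≥ 1. Steady levels are
μ/α, so α < 1 can push levels above 1; following the formalism's
convention such values are passed through connectives and membership
unclipped.

### Numerics

Integration is fixed-step classical Runge–Kutta (RK4) with dt = 0.01
time units by default; the contract is the grid-refinement invariant
(halving dt moves converged levels by < 1e−6), not the specific
stepper. An explicit Euler stepper is available and is the
deterministic limb of the Langevin scheme. Steady-state detection
requires the max-norm residual ‖dq/dt‖∞ to stay below the tolerance
(default 1e−6) for a full hold window (default 10 time units);
sustained oscillation is flagged when the per-window residual maxima
fail to decrease across two consecutive windows. Damped oscillation
of a node is defined as ≥ 2 strict interior local maxima, each lower
than its predecessor, on the recorded trajectory.

### Boolean–fuzzy correspondence

With all α = 1 and β = 200, every Boolean fixed point is a continuous
steady state by construction (at a binary vertex each w_k is exactly
0 or 1, so μ ≈ q_k to within e^(−β/2)). The converse check integrates
from every binary vertex and rounds each *converged* steady state at
threshold 1/2. One genuine subtlety: exactly symmetric initial
conditions can relax onto the no-contradiction saddle where some node
sits at exactly 1/2 (the toggle switch from (0,0) or (1,1) is the
canonical case — the two mutual repressions cancel along the
diagonal). Rounding is undefined at the threshold, so states with a
component within 1e−3 of 1/2 are reported as "threshold states"
rather than counted as mismatches. Runs that neither converge nor
settle (the fuzzified negative circuits) are counted separately; they
correspond to the Boolean cyclic attractors, which the limit claim
deliberately excludes.

### NF-kB relaxation and the slow-transcription sweep

The NF-kB fixture (TNFα → IKK; IKK and IkBa gating p65_RelA; p65_RelA
→ tIkBa → IkBa) has, discretely, one resting fixed point without TNFα
and two limit cycles under stimulation. Continuously, at β = 3 under
sustained TNFα the system always converges to a regulated p65 level.
Whether it rings on the way depends on the transcription node's decay
rate: the package's sweep over α_tIkBa ∈ {0.2, 0.5, 1.0} finds
underdamped relaxation (strictly decreasing successive p65 maxima)
at 0.5 and 1.0, while at 0.2 the slow mode detaches and the loop gain
— reduced by the saturation of the amplified transcript level
μ/α ≈ 1.45 — leaves all Jacobian eigenvalues real: a single overshoot
followed by monotone convergence. The acceptance checks therefore
assert that damped oscillations are recorded *within the sweep* and
that the slow-transcription point converges to the regulated steady
state; they do not assert ringing at α_tIkBa = 0.2 itself, where the
linearization rules it out.

## Stochastic extension

The Langevin dynamics adds independent Gaussian white noise ξ_k(t)
with ⟨ξ(t)ξ(t′)⟩ = D δ(t−t′) to every free node (inputs are boundary
conditions and receive none). Paths use Euler–Maruyama — the noise is
additive, so the Itô/Stratonovich distinction is moot — with per-step
increments √(D·dt)·N(0,1). At D = 0 the scheme reproduces the
deterministic Euler path bit-for-bit. Levels are floored at 0 after
each step (expression cannot be negative); the upper side is left
unclipped, consistent with the α < 1 convention. The floor biases the
ensemble mean of fully silenced nodes upward by the one-sided
fluctuation scale ~√(2/π)·√(D/2α) (≈ 0.056 at D = 0.01, α = 1);
interior nodes track the deterministic path to well within 0.05 at
that intensity. One root seed spawns per-path streams deterministically
(`default_rng([seed, path_index])`), so ensembles are reproducible and
paths uncorrelated.

## Model reduction

A node is collapsed when its absorption-simplified rule depends on
exactly one *other* node and the node lies on no feedback circuit
(strongly connected component membership, self-loops included);
removal substitutes its rule into every referencing rule and
re-simplifies. Removal proceeds in deterministic node (file) order to
a fixed point, and the report keeps each removed node's back-substituted
expression over retained nodes, so steady values are recoverable.
Fixed points are preserved exactly — at a fixed point the substitution
is an identity — and this is asserted by exhaustive enumeration of
both models. Cyclic attractors under synchronous update are *not*
preserved in general (collapsing a relay shortens the feedback delay,
changing periods and counts), so cycle counts are reported
informationally, never asserted.

## Fixtures and the random-network generator

The bundled fixtures are reconstructions of small published circuits
from their described interactions, chosen to be the minimal rule sets
reproducing the reported attractor structure:

- `bpc` — B-cell/plasma-cell core: AP1 = LPS ∧ ¬Bcl6;
  Blimp1 = AP1 ∧ ¬Bcl6 ∧ ¬Pax5; Pax5 = ¬Blimp1; Bcl6 = ¬Blimp1.
  Yields exactly the B-cell (Pax5, Bcl6) and plasma-cell (Blimp1, AP1)
  fixed points over both LPS conditions.
- `nfkb` — IKK = TNFa; p65_RelA = IKK ∧ ¬IkBa; tIkBa = p65_RelA;
  IkBa = tIkBa. Gating IkBa by ¬IKK instead would make the stimulated
  state a fixed point, contradicting the reported two stimulated limit
  cycles; this variant was checked and rejected.
- `toggle`, `negring3` — the minimal positive (bistable) and negative
  (oscillatory) circuits used by the circuit-theorem property tests.

The random generator draws a preferential-attachment skeleton
(Barabási–Albert, attachment parameter 2 by default), orients each
edge uniformly, guarantees ≥ 1 regulator per node, forbids
self-loops, and assembles rules as random AND/OR trees over possibly
negated regulators. It emulates the heavy-tailed connectivity of
biological GRNs but none of their functional organisation (no
canalyzing bias, no enrichment for feedback structure); property
results on these instances support the algebraic claims
(correspondence, reduction, basin partition), not biological realism.
All generation is bit-reproducible from (n, seed, wiring).

## Problem sizes

The test and acceptance runs use the four fixtures (≤ 5 nodes, ≤ 32
states per condition), random networks of 4–10 nodes, integrations of
50–400 time units at dt = 0.01, and Langevin ensembles of up to 200
paths — sizes at which every enumeration is exhaustive and every
continuous result is grid-converged.

## Known limitations

Synchronous updating only; no SAT/BDD attractor detection, so state
spaces beyond 2^22 require reduction first; no bifurcation
continuation or quasi-potential landscape computation; no
Fokker–Planck solution of the level distribution; rule files are the
package's own bnet-style dialect (no SBML-qual import).
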