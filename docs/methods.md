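# Methods

## Model formalism

`hillnet` implements logic-based differential equations (LDEs): a
continuous relaxation of Boolean network models in which each species
*i* carries a normalized activity *y_i* and relaxes toward a
logic-determined target,

    dy_i/dt = ( φ_i(y) · y_max_i − y_i ) / τ_i .

The drive φ_i ∈ [0, 1] is assembled in three layers:

1. **Edges.** An activating term with source activity *x* contributes the
   normalized Hill function f(x) = β xⁿ / (Kⁿ + xⁿ); an inhibiting term
   contributes 1 − f(x). β and K are not free: they are the unique
   solution of the anchors f(0) = 0, f(EC50) = ½, f(1) = 1, namely
   Kⁿ = EC50ⁿ / (1 − 2·EC50ⁿ) and β = 1 + Kⁿ. The parameterization
   exists iff 0 < EC50 < 1 and EC50ⁿ < ½; both validation and
   `hill_shape` enforce this (EC50 = 0.5 with n = 1 sits exactly on the
   boundary and is rejected). The closed form is verified in the test
   suite against an independent 2-D root-finding oracle.
2. **AND within a rule.** Terms joined by `&` multiply (fuzzy product).
   A rule whose antecedents are all inhibitors therefore gives full
   drive while its repressors are off — which is how a species like ISL1
   can start at activity 1 sustained solely by the absence of NKX2-5.
3. **OR across rules.** Reactions sharing a target fold with the
   probabilistic OR, a ⊕ b = a + b − ab. This is associative,
   commutative (order-invariance is property-tested to 1e-12) and
   smooth, which keeps the right-hand side Lipschitz and the integrator
   happy; `max` would introduce derivative kinks. Input reactions
   (empty antecedent) contribute their weight directly.

The flow never leaves the box [0, y_max] componentwise: φ ∈ [0, 1]
implies dy_i/dt ≥ −y_i/τ_i at the lower face and
dy_i/dt ≤ (y_max_i − y_i)/τ_i at the upper face. Knockouts are modeled
by y_max = 0, which makes the species decay to zero and stay there
regardless of its inputs.

One convention was genuinely open: whether to clamp the weighted flux at
*w* or the unweighted activation at 1 when a source activity exceeds 1
(possible when y_max > 1). The two are indistinguishable for the weights
0 and 1 used throughout the bundled models; we clamp the unweighted
activation so a flux always reads as "weight × logic level".

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| τ | relaxation time constant per species | 1 | arbitrary time |
| y_init | activity at simulation start | 0 | dimensionless |
| y_max | maximal activity (0 = knockout) | 1 | dimensionless |
| w | reaction weight / stimulus strength | 1 (inputs in bundled models start at 0) | dimensionless, [0, 1] |
| n | Hill steepness | 1.4 | dimensionless |
| EC50 | half-maximal source activity | 0.5 | dimensionless |

Defaults are the established conventions of the workbook dialect; the
bundled networks use them untouched. Weights outside [0, 1] are
rejected — a weight is an edge probability/strength, not a gain.

## Numerics

Integration uses an adaptive explicit Runge-Kutta method
(`scipy.integrate.solve_ivp`, RK45) with rtol 1e-6 and atol 1e-8. The
dynamics are smooth, bounded and non-stiff, so any conforming adaptive
explicit method would do; the single-input closed form
y(t) = y_max(1 − e^(−t/τ)) is reproduced to ~1e-5 and chained segments
agree with a single long segment to better than 1e-6. Output is reported
on an even grid of 101 points per segment (including both endpoints);
protocol continuation always uses the integrator's exact final state,
never a grid-interpolated value, so interpolation error cannot compound
across segments. When segments are concatenated, the duplicated boundary
row is dropped so the global time axis stays strictly increasing;
segment boundaries are recorded separately.

Steady states are found by integrating to convergence
(max_i |dy_i/dt|·τ_i < 1e-6, capped at 500·max τ) rather than algebraic
root-finding: integration is robust to multistability and matches how
staged protocols reach their end states. Non-convergence (possible for
oscillatory feedback networks) is reported as a flag, never an error.

Default segment duration is 10 time units — a few time constants, enough
for saturation at the default τ = 1 — and is configurable per step.

## Protocols and the knockout screen

A protocol is an ordered list of (duration, parameter changes). Changes
are step functions applied instantaneously at segment boundaries,
mirroring the interactive change-weight-then-simulate workflow, and
persist across later steps; a "reset" is simply a fresh protocol run.
All step changes are validated before any integration so a typo in step
5 cannot waste the first four segments.

The systematic knockout screen computes a stimulated baseline steady
state (every input reaction's weight set to 1 unless overridden), then
re-computes the steady state with each target species' y_max set to 0,
reporting knockout − baseline deltas. Rows are ordered by species index
whatever order targets are given in, so screens are deterministic.

## Workbook format choices

Header rows are located by content (a row containing `ID` plus `Yinit`
or `Rule`), not by fixed position, because published workbooks of this
dialect carry decorative preamble rows. Error messages use 1-based
sheet/row coordinates. Rule cells beginning with `=` are written with a
leading apostrophe so spreadsheet software keeps them as text, and the
apostrophe is stripped unconditionally on read. Unrecognized columns
round-trip verbatim as per-row metadata; empty metadata cells are
treated as absent. Species ids are ASCII tokens
(`[A-Za-z_][A-Za-z0-9_]*`); display names may contain arbitrary Unicode
(e.g. "NKX2-5" as a name for id `NKX25`). Workbooks are expected to
already contain valid tokens — no id sanitization is attempted, since
any sanitization rule would be a guess that silently rewrites a model.

Cytoscape export writes one SIF line per rule term
(`SOURCE activates|inhibits TARGET`); input reactions appear as
pseudo-source nodes `INPUT_<target>` because SIF requires a source node
and stimuli should stay visible in the rendered network.

## Random-model generator

`random_network` builds reproducible valid models for property tests:
the first reaction is always an input (so some drive exists), later
reactions are inputs with probability `p_input` or 1-3-term rules whose
terms inhibit with probability `p_inhib`; weights are uniform on [0, 1]
and all other parameters stay at the defaults. Isolated species are
allowed deliberately — they exercise zero-drive exponential decay. The
generator emulates the *structure* of hand-curated signaling networks,
not their biology: it has no modularity, no degree heterogeneity and no
enrichment for coherent feed-forward motifs, so passing property tests
(boundedness, oracle agreement, determinism) says the mathematics is
implemented correctly, not that any particular biological prediction is
right.

## Limitations

- Only AND (`&`) and negation (`!`) exist in the rule grammar; OR is
  expressed by multiple reactions sharing a target. Multi-valued logic,
  explicit OR syntax, delays and stochastic semantics are out of scope.
- Steady states are numerical; a network poised on an unstable manifold
  or oscillating will come back flagged unconverged rather than solved.
- The integrator contract assumes non-stiff dynamics, which holds for
  bounded Hill nonlinearities with moderate n; extremely large Hill
  coefficients would sharpen the sigmoids toward step functions and
  eventually deserve a stiff solver.
- Spreadsheet export of executable MATLAB/Python model code and GUI
  rendering are not provided; SIF export targets Cytoscape instead.
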