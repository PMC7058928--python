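# Methods

This note documents the models implemented in norcad, the defaults and
their provenance, the synthetic-data assumptions, and the design choices
made where the problem was genuinely open.

## Steady-state gate model

Signals are RNAP fluxes in relative promoter units (RPU); no conversion
to absolute transcript or molecule counts is attempted anywhere. A gate's
response to total input flux x is the declining Hill function
`y = y_min + (y_max − y_min)·Kⁿ/(Kⁿ + xⁿ)`, implemented in the
algebraically equivalent form `y = y_max − (y_max − y_min)·xⁿ/(Kⁿ + xⁿ)`
so that the unrepressed limit (x = 0) is exactly `y_max` in floating
point; outputs then satisfy `y_min < y ≤ y_max` strictly.

Tandem composition. For two promoters in series, the upstream (position
1) flux is attenuated by the downstream (position 2) promoter:
`x = f·x₁ + x₂` with `f = α·(Kⁿ + β·x₂ⁿ)/(Kⁿ + x₂ⁿ)` evaluated with the
*downstream* driver's parameters at its own input. f decreases
monotonically from α (repressor unbound) to α·β (fully bound). The
microscopic kinetics behind β (repressor off-rate versus RNAP dissociation)
are deliberately not modeled; β is a fitted lumped constant. Position
labels are explicit in the netlist; synthesis assigns the
lexicographically smaller driver to position 1, a pure convention since
no placement restriction applies.

Sensor promoters sitting downstream are two-state: a repressor-based
sensor contributes α when induced and α·β when not; an activator-based
sensor always contributes α. Per-sensor α/β values are not published, so
the packaged library sets them to 1 (additive behavior) and flags this in
its metadata; users can override them in the library file.

A NOT node feeds its single input directly into the Hill response; an
output stage with two drivers composes them with the same tandem rule as
a NOR input pair (the reporter's OR stage *is* a tandem promoter pair).

Scoring. A circuit's separation score is min(required-ON flux) /
max(required-OFF flux) over the state table, don't-care rows excluded;
values above 1 mean every ON state outshines every OFF state. The exact
scoring function used by existing design tools is not published; this
conventional ratio is isolated behind `circuit_score` so it can be
swapped.

## The packaged library

`builtin_library()` ships 18 gates across 10 repressor families with
their Hill parameters, interference factors (α, β), and switching
timescales; the same values are checked in as a plain TSV
(`data/gate_parameters.tsv`) and the test suite asserts the two agree
field-for-field. Sensor OFF/ON levels: P_Tac 0.008/1.686, P_Tet
0.04/1.967, P_Lux2 0.03/2.234, P_Cin 0.005/3.178 RPU. Layout rules:
enforced family order VanR→…→CymR, scar order A B D E F X V U C with A/C
flanking, at most one gate per family per circuit, and CymR:SrpR
prohibited from co-occurring.

Two quantities needed by the dynamic model are not published and were
fixed once at field-typical values: sensor induction timescales
(`tau_induction = 1.0 /h`, the middle of the gates' own 0.15–11 /h range)
and reporter turnover (`degradation_rate = 0.5 /h`, with
`production_scale = 1` so a constant output flux F drives the reporter to
F, keeping traces on the RPU scale).

## Logic synthesis

The hardware basis is {NOT, NOR2} with fan-in 2 (a cassette holds at most
two input promoters) plus a free 2-input OR at the output stage (two
output promoters in tandem before the reporter). Don't-care rows are
exploited in both modes; the 7-segment fixtures mark non-decimal codes
10–15 don't-care by default (overridable), following the classic decoder
chips whose patterns they reproduce (6 without segment A, 9 without D).

* `enumerate`: iterative-deepening exhaustive search over gate counts
  with truth-signature deduplication; provably minimal, exponential, and
  intended for small instances (it is cross-checked against an
  independent brute force for all 2-input functions).
* `minimize`: candidate generation followed by ranking. Candidates come
  from Quine–McCluskey two-level forms (SOP and POS, for the function and
  its complement) mapped onto the NOR basis with structural sharing, and
  from Shannon cofactor expansions — both the sum form
  OR(AND(v,f₁), AND(v',f₀)) and the product form
  AND(OR(v,f₀), OR(v',f₁)), selectable per recursion depth — over all
  variable orders, with reuse of any previously built signal that is
  *compatible* with a target under its don't-cares. Every candidate is
  verified against the specification before ranking.

Ranking is (gate count, circuit depth, NOT count, canonical text), which
makes output deterministic and prefers shallow circuits among equal-size
realizations — the two-NOT/tandem-OR NAND over the equal-size
one-NOT/one-NOR chain, matching the physically characterized test
circuits. On the seven display segments, `minimize` yields 3–8 gates per
circuit, within the 10-family assignment budget.

## Gate assignment

Feasibility = one gate per repressor family plus no prohibited pair.
The optimizer maximizes the separation score under the interference model
(the additive model on request). Instances whose exact feasible-assignment
count (computed combinatorially) is at most 50,000 are solved
exhaustively with a canonical lexicographic tie-break; larger ones use
seeded simulated annealing: proposals reassign one node or swap two,
acceptance is Metropolis on log-score, the initial temperature is half
the log-score spread of 100 random feasible assignments, and the
temperature cools by 0.98 every 25 steps over 10,000 steps. The
exhaustive/anneal threshold of 50,000 keeps a full 7-segment design run
in tens of seconds in pure Python while leaving every ≤4-node instance
exact; both the threshold and the schedule are exposed in `options`.
Scoring inside the optimizer uses a precompiled flat evaluator that the
test suite pins to the reference path bit-for-bit.

## Dynamics

Each gate relaxes toward the steady state implied by its instantaneous
input with `dy/dt = τ·(y_ss − y)`, where τ = τ_on if y < y_ss and τ_off
otherwise (at y = y_ss the derivative vanishes either way, so the tie is
inert). y_ss is computed from the *current* (not steady-state) upstream
outputs through the interference composition — i.e., per-output-promoter
ODEs coupled through instantaneous steady-state responses. Sensors relax
with a single timescale toward their OFF/ON level; the reporter follows
`dY/dt = γ·(production_scale·F − Y)` with F the composed output flux.
Integration uses LSODA segment-by-segment (state continuous across
segment boundaries; only sensor targets switch), rtol 1e-8 / atol 1e-10,
output grid 0.1 h by default; all exposed via `solver_options`. The
initial condition is the steady state of the first schedule segment
unless overridden. Single-gate trajectories agree with the closed-form
exponential to 1e-6 relative, and long-horizon simulations land on the
steady-state solver to 1e-4.

## Power accounting

`J_RNAP` sums the flux of every promoter instance physically on the
construct: one term per (driver, consumer) edge — each tandem input
promoter separately, with the interference factor applied to the upstream
member of a pair — plus the output promoter(s) driving the reporter.
Constitutive regulator expression on the sensor plasmid is excluded: it
is constant, off-construct, and not part of the state-dependent draw.
The module only reports the metric; no "safe" threshold is asserted
because no defensible value exists.

## Parameter fitting and synthetic data

* Dose-response (Hill): bounded trust-region least squares on
  log-residuals (outputs span ~3 decades and errors are ratio-like),
  parameterized as (y_min, y_max−y_min, K, n) so the ordering constraint
  is structural; n bounded to [0.5, 8]; 10 seeded multi-starts guard the
  multimodal n surface. Near-constant data are flagged non-identifiable
  rather than raising.
* Interference (α, β): least squares of the tandem composition against
  the four-point quadrant experiment (upstream promoter low/high ×
  downstream gate input low/high), both parameters bounded above by 1
  with boundary hits flagged. Residuals are linear — with four points the
  weighting choice is immaterial for the noise-free fit, and a log-space
  variant was checked to give indistinguishable noisy behavior.
  A genuine identifiability limit exists here: α enters only the
  upstream-ON/downstream-OFF observation, where a high-y_max gate buries
  the α·(upstream flux) term under its own unrepressed output, so for
  such gates multiplicative noise of 5% propagates to σ_α ≈ 0.19
  regardless of estimator. Recovery under noise is therefore tested on a
  low-background gate, where the four-point design is informative.
* Timescales: one τ fitted per experiment direction by forward-simulating
  the sensor → gate → reporter chain and matching the reporter trace
  normalized to its t = 0 value (hence scale-invariant); a coarse
  log-grid start precedes bounded refinement.

Generators produce data from exactly these forward models with
median-preserving multiplicative lognormal noise
(σ² = ln(1+CV²)), the conventional error model for flow-cytometry
medians; zero CV returns exact model values and a fixed seed reproduces
datasets byte-for-byte. The default sweep uses 18 input levels
(geometric, 0.005–5 RPU), mirroring the 18-concentration characterization
protocol. The 20-circuit tandem validation roster (all ordered pairs of
the first five distinct-family gates) is a deterministic synthetic
stand-in for the unpublished experimental roster: it reproduces the suite
size (20 circuits × 4 inducer states = 80 predictions) and structure, not
the specific plasmids.

What the generators do *not* emulate: cell-to-cell cytometry
distributions, growth-rate feedback and dilution, replicate structure,
wash/resuspension artifacts between schedule segments, and
plasmid-copy-number variation. Passing recovery tests therefore
demonstrate correctness of the estimators against the stated noise model,
not robustness to these real-data effects.

## Known limitations

* Sensor interference parameters default to additive (α = β = 1); any
  conclusions about sensors in downstream tandem positions inherit this.
* The `minimize` synthesizer is near-minimal, not provably minimal, for
  3–4 inputs; `enumerate` is exact but exponential.
* Annealing is stochastic: for instances above the exhaustive threshold
  the returned assignment is the best found under the seed, bounded above
  by the true optimum (verified on small instances).
* The power inventory counts circuit-construct promoters only; the
  high-copy-backbone comparison reported experimentally cannot be
  reproduced because those parameters are unpublished.
* Growth impact (OD600) prediction is out of scope; `od_to_cfu` is a
  standalone calibration utility for display loading.
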