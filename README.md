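# norcad

Design automation for transcriptional NOR-gate genetic circuits in
*Escherichia coli*, built around a gate model that goes beyond additive
promoter arithmetic: it accounts for **tandem-promoter interference**
(repressor roadblocking), **two-timescale switching dynamics**, and the
circuit's total **RNA-polymerase flux** (a "power" metric for host burden).
The package is written for synthetic biologists and modelers who design
repressor-based logic circuits from characterized gate libraries — the
worked example throughout is a binary-coded-decimal to 7-segment decoder
distributed across seven bacterial strains.

## The model

All signals are RNA-polymerase fluxes in relative promoter units (RPU).
A gate is a repressor cassette whose output promoter responds to the total
input flux *x* with a declining Hill function

```
y(x) = y_min + (y_max − y_min) · Kⁿ / (Kⁿ + xⁿ)
```

A NOR gate carries two input promoters in series. The additive
approximation sums their fluxes, `x = x₁ + x₂`; in reality the downstream
promoter (position 2) suppresses read-through from the upstream one
(position 1). When the downstream gate's repressor is bound it physically
roadblocks elongating RNAP; the corrected composition is

```
x = α · (Kⁿ + β·x₂ⁿ) / (Kⁿ + x₂ⁿ) · x₁  +  x₂
```

where α ∈ (0,1] is the repressor-independent (non-specific) suppression,
β ∈ (0,1] the roadblock factor, and K, n, x₂ belong to the downstream
driver. With α = β = 1 this reduces exactly to the additive model.

Dynamics use one first-order timescale per direction,

```
dy/dt = τ_on · (y_ss − y)   if y < y_ss      (transcription-limited rise)
        τ_off · (y_ss − y)  otherwise        (repressor-decay-limited fall)
```

and the circuit's power draw is `J_RNAP = Σ` flux over every promoter
instance physically present on the construct.

The packaged library transcribes the characterization of 18 repressor
gates (10 families), four inducible sensors (P_Tac, P_Tet, P_Lux2, P_Cin),
the reporter kinetics, and the Eugene-style layout rules (enforced family
order, scar order A…C, the CymR:SrpR orthogonality prohibition, one gate
per family).

## Worked example: one display segment

Segment E of a 7-segment display must light for digits {0, 2, 6, 8}
(rows 10–15 are don't-care). Design it against the packaged library:

```python
import norcad
lib = norcad.builtin_library()
res = norcad.design(norcad.seven_segment_spec("E"), lib, seed=1,
                    sensors=norcad.DISPLAY_SENSORS)
print(res.layout.to_text(), res.score)
```

prints

```
[A]--P2-PhlF--[B]--H1-HlyIIR_2--[D]--E1-BetI_2--[C]
179.50868539035454
```

a three-gate circuit (two NORs and a NOT, with a free tandem-promoter OR
at the reporter) whose separation score is 179.5: the dimmest required-ON
state (1.13 RPU, digit 0) is 179× brighter than the brightest
required-OFF state (0.0063 RPU). The full 16-row state table is in
`res.table.to_tsv()`. The same flow is available from the shell:

```sh
norcad design segment_E.tsv --seed 1 --out-dir out/
norcad simulate out/netlist.txt out/assignment.txt --schedule cycle.tsv
norcad od2cfu 1.0          # -> 2e+09
```

Single-gate arithmetic is equally direct: for the P1-PhlF gate,
`hill_response(g, 0.0) = 6.9` (unrepressed), `hill_response(g, 1.686) =
0.0040` (fully repressed by an induced P_Tac input), and
`roadblock_factor(g, 1.686) = 0.0132` — an induced PhlF promoter sitting
downstream passes only 1.3% of its tandem partner's flux.

## Layout

| module | contents |
| --- | --- |
| `norcad.gate_library` | records, validation, UCF-style JSON I/O, packaged fixture |
| `norcad.steady_state` | Hill response, roadblock factor, tandem composition, circuit evaluation, scoring |
| `norcad.logic_synthesis` | truth tables → NOT/NOR2 netlists (exact enumeration + heuristic minimization) |
| `norcad.assignment` | feasibility rules, exhaustive/annealed gate assignment, construct layout |
| `norcad.dynamics` | inducer schedules, ODE simulation, closed-form relaxation |
| `norcad.power` | per-promoter RNAP-flux inventory, state and trajectory power |
| `norcad.parameter_fitting` | Hill / interference / timescale fitters, synthetic-data generators |
| `norcad.examples` | 7-segment truth tables, digit-cycle schedule, tandem suite |
| `norcad.cli` | `norcad` command-line entry points, OD→CFU calibration |

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
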