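"""Gate-to-node assignment under library feasibility rules.

Feasibility mirrors the library's layout constraints: at most one gate per
repressor family in a circuit (gates in a family differ only by RBS or
promoter variant and would cross-talk), and declared non-orthogonal family
pairs may not co-occur.  The optimizer maximizes the circuit separation
score (min required-ON flux over max required-OFF flux) computed under the
interference model by default.

Small instances are solved exhaustively; larger ones by seeded simulated
annealing over single-node reassignments and pairwise swaps.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .errors import AssignmentError, CapacityError, ValidationError
from .gate_library import GateLibrary, GateRecord
from .steady_state import (INPUT, INTERFERENCE, NOR2, NOT, Assignment,
                           CircuitNetlist)

__all__ = ["feasible", "optimize", "layout", "LayoutPlan",
           "count_feasible_assignments", "compile_scorer"]


# --------------------------------------------------------------------------
# Feasibility
# --------------------------------------------------------------------------

def feasible(assignment: Assignment, library: GateLibrary
             ) -> tuple[bool, list[str]]:
    """Check family-uniqueness and prohibited-pair rules."""
    violations: list[str] = []
    families: dict[str, list[str]] = {}
    for node, gname in sorted(assignment.node_to_gate.items()):
        try:
            gate = library.gate(gname)
        except KeyError as exc:
            raise AssignmentError(str(exc)) from exc
        families.setdefault(gate.repressor_family, []).append(node)
    for fam, nodes in sorted(families.items()):
        if len(nodes) > 1:
            violations.append(
                f"repressor family {fam!r} assigned to multiple nodes: "
                f"{', '.join(nodes)}")
    present = set(families)
    for pair in library.layout.prohibited_pairs:
        if pair <= present:
            a, b = sorted(pair)
            violations.append(f"prohibited gate pair co-assigned: {a}:{b}")
    return (not violations, violations)


def count_feasible_assignments(n_nodes: int, library: GateLibrary) -> int:
    """Exact count of feasible total assignments for an n-node netlist."""
    byfam = library.gates_by_family()
    fams = sorted(byfam)
    total = 0
    for combo in combinations(fams, n_nodes):
        combo_set = set(combo)
        if any(p <= combo_set for p in library.layout.prohibited_pairs):
            continue
        prod = 1
        for f in combo:
            prod *= len(byfam[f])
        total += prod
    return total * math.factorial(n_nodes)


# --------------------------------------------------------------------------
# Fast scorer
# --------------------------------------------------------------------------

class compile_scorer:
    """Precompiled score evaluator for one netlist/library/model/spec.

    Evaluating an assignment reduces to a flat loop over topologically
    ordered operations with plain floats; this is the hot path of both the
    exhaustive search and the annealer and agrees exactly with
    ``truth_table_prediction`` + ``circuit_score``.
    """

    def __init__(self, netlist: CircuitNetlist, library: GateLibrary,
                 model: str = INTERFERENCE, spec=None):
        self.netlist = netlist
        self.library = library
        self.model = model
        order = netlist.topological_order()
        self.gate_nodes = [name for name in order
                           if netlist.node(name).kind in (NOT, NOR2)]
        gpos = {name: i for i, name in enumerate(self.gate_nodes)}
        n = netlist.n_inputs

        if spec is not None:
            required = list(spec.outputs)
        else:
            from .steady_state import boolean_outputs
            required = ["ON" if b else "OFF"
                        for b in boolean_outputs(netlist)]
        self.on_rows = [k for k, r in enumerate(required) if r == "ON"]
        self.off_rows = [k for k, r in enumerate(required) if r == "OFF"]

        # Per state: precompute sensor fluxes/occupancies, and the op list.
        # op = (target_idx_or_None, src1, src2) where src = ("const", v, occ)
        # or ("node", gate_idx); target None marks the OUTPUT composition.
        from .steady_state import sensor_occupancy
        self.states = []
        inputs = netlist.inputs
        for k in range(2 ** n):
            bits = {nd.name: (k >> i) & 1 for i, nd in enumerate(inputs)}
            const: dict[str, tuple[float, float]] = {}
            for nd in inputs:
                sensor = library.sensor(nd.sensor)
                on = bool(bits[nd.name])
                const[nd.name] = (sensor.on_rpu if on else sensor.off_rpu,
                                  sensor_occupancy(sensor, on))
            ops = []
            for name in order:
                nd = netlist.node(name)
                if nd.kind == INPUT:
                    continue
                srcs = []
                for p in nd.parents:
                    if p in const:
                        srcs.append(("const",) + const[p])
                    else:
                        srcs.append(("node", gpos[p]))
                ops.append((gpos.get(name), tuple(srcs)))
            self.states.append(ops)

    def params(self, gate: GateRecord) -> tuple:
        return (gate.y_max, gate.y_max - gate.y_min, gate.K ** gate.n,
                gate.n, gate.alpha, gate.beta)

    def score(self, gate_vector: Sequence[tuple]) -> float:
        """Score an assignment given per-gate-node parameter tuples (in
        ``self.gate_nodes`` order)."""
        interference = self.model == INTERFERENCE
        outputs: list[float] = [0.0] * len(gate_vector)
        occs: list[float] = [1.0] * len(gate_vector)
        fluxes: list[float] = []
        for ops in self.states:
            out_flux = 0.0
            for target, srcs in ops:
                if len(srcs) == 1:
                    tag = srcs[0]
                    x = tag[1] if tag[0] == "const" else outputs[tag[1]]
                else:
                    up, down = srcs
                    u = up[1] if up[0] == "const" else outputs[up[1]]
                    if down[0] == "const":
                        d, occ = down[1], down[2]
                    else:
                        d, occ = outputs[down[1]], occs[down[1]]
                    x = (occ * u + d) if interference else (u + d)
                if target is None:
                    out_flux = x
                else:
                    ymax, dy, kn, nn, alpha, beta = gate_vector[target]
                    xn = x ** nn
                    outputs[target] = ymax - dy * xn / (kn + xn)
                    occs[target] = alpha * (kn + beta * xn) / (kn + xn)
            fluxes.append(out_flux)
        mn = min(fluxes[k] for k in self.on_rows)
        mx = max(fluxes[k] for k in self.off_rows)
        return mn / mx


# --------------------------------------------------------------------------
# Optimization
# --------------------------------------------------------------------------

_DEFAULTS = {
    "exhaustive_threshold": 50_000,  # feasible-assignment count switch
    "anneal_steps": 10_000,
    "cooling": 0.98,
    "steps_per_temperature": 25,
}


def _feasible_vector(names: Sequence[str], library: GateLibrary) -> bool:
    fams = [library.gate(g).repressor_family for g in names]
    if len(set(fams)) != len(fams):
        return False
    present = set(fams)
    return not any(p <= present
                   for p in library.layout.prohibited_pairs)


def optimize(netlist: CircuitNetlist, library: GateLibrary,
             model: str = INTERFERENCE, method: str = "auto",
             seed: int = 0, options: dict | None = None,
             spec=None) -> tuple[Assignment, float]:
    """Find a feasible assignment maximizing the separation score.

    ``method`` is "exhaustive", "anneal", or "auto" (exhaustive when the
    feasible-assignment count is below the configured threshold).
    Annealing is reproducible for a fixed seed.  ``spec`` optionally
    supplies required output levels with don't-cares; otherwise the
    netlist's Boolean semantics define them.
    """
    opts = dict(_DEFAULTS)
    opts.update(options or {})
    nodes = [name for name in netlist.topological_order()
             if netlist.node(name).kind in (NOT, NOR2)]
    m = len(nodes)
    if m == 0:
        raise AssignmentError("netlist has no logic nodes to assign")
    n_fams = len(library.families())
    if m > n_fams:
        raise CapacityError(
            f"netlist needs {m} gates but the library has only {n_fams} "
            "repressor families (at most one gate per family per circuit)")

    scorer = compile_scorer(netlist, library, model=model, spec=spec)
    gates = list(library.gates)
    params = {g.name: scorer.params(g) for g in gates}

    def vec_score(names: Sequence[str]) -> float:
        return scorer.score([params[g] for g in names])

    if method == "auto":
        count = count_feasible_assignments(m, library)
        method = ("exhaustive" if count <= opts["exhaustive_threshold"]
                  else "anneal")

    if method == "exhaustive":
        best_names, best_score = _exhaustive(nodes, gates, library, vec_score)
    elif method == "anneal":
        best_names, best_score = _anneal(nodes, gates, library, vec_score,
                                         seed, opts)
    else:
        raise ValueError(f"unknown method {method!r}")

    assignment = Assignment(node_to_gate=dict(zip(nodes, best_names)))
    ok, violations = feasible(assignment, library)
    assert ok, violations
    return assignment, best_score


def _exhaustive(nodes, gates, library, vec_score):
    best_names, best_score = None, -math.inf
    m = len(nodes)
    gate_names = [g.name for g in gates]
    fams = {g.name: g.repressor_family for g in gates}
    prohibited = library.layout.prohibited_pairs
    chosen: list[str] = []
    used_fams: list[str] = []

    def rec(depth: int):
        nonlocal best_names, best_score
        if depth == m:
            s = vec_score(chosen)
            # canonical tie-break: lexicographically smallest name tuple
            if s > best_score or (s == best_score and
                                  tuple(chosen) < tuple(best_names)):
                best_names, best_score = list(chosen), s
            return
        for gname in gate_names:
            fam = fams[gname]
            if fam in used_fams:
                continue
            if any(pair <= set(used_fams) | {fam} for pair in prohibited):
                continue
            chosen.append(gname)
            used_fams.append(fam)
            rec(depth + 1)
            chosen.pop()
            used_fams.pop()

    rec(0)
    if best_names is None:
        raise CapacityError("no feasible assignment exists for this "
                            "netlist/library pair")
    return best_names, best_score


def _random_feasible(nodes, gates, library, rng) -> list[str]:
    byfam = library.gates_by_family()
    for _ in range(1000):
        fams = rng.sample(sorted(byfam), len(nodes))
        if any(p <= set(fams) for p in library.layout.prohibited_pairs):
            continue
        return [rng.choice(sorted(g.name for g in byfam[f])) for f in fams]
    raise CapacityError("could not draw a feasible random assignment")


def _anneal(nodes, gates, library, vec_score, seed, opts):
    rng = random.Random(seed)
    gate_names = sorted(g.name for g in gates)
    m = len(nodes)

    current = _random_feasible(nodes, gates, library, rng)
    cur_s = vec_score(current)
    best, best_s = list(current), cur_s

    # initial temperature from the log-score spread of random assignments
    samples = []
    for _ in range(100):
        v = _random_feasible(nodes, gates, library, rng)
        samples.append(math.log10(max(vec_score(v), 1e-300)))
    spread = max(samples) - min(samples) if samples else 1.0
    temp = max(spread / 2.0, 0.05)

    steps = int(opts["anneal_steps"])
    per_temp = int(opts["steps_per_temperature"])
    cooling = float(opts["cooling"])
    for step in range(steps):
        cand = list(current)
        if m >= 2 and rng.random() < 0.3:
            i, j = rng.sample(range(m), 2)
            cand[i], cand[j] = cand[j], cand[i]
        else:
            i = rng.randrange(m)
            cand[i] = rng.choice(gate_names)
        if not _feasible_vector(cand, library):
            continue
        s = vec_score(cand)
        delta = math.log10(max(s, 1e-300)) - \
            math.log10(max(cur_s, 1e-300))
        if delta >= 0 or rng.random() < math.exp(delta / temp):
            current, cur_s = cand, s
            if s > best_s or (s == best_s and tuple(cand) < tuple(best)):
                best, best_s = list(cand), s
        if (step + 1) % per_temp == 0:
            temp = max(temp * cooling, 1e-4)
    return best, best_s


# --------------------------------------------------------------------------
# Linear layout
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LayoutPlan:
    """Linear construct plan: scar, gate, scar, gate, ..., closing scar."""

    entries: tuple[tuple[str, str], ...]  # (scar before gate, gate name)
    closing_scar: str = "C"

    def to_text(self) -> str:
        toks: list[str] = []
        for scar, gate in self.entries:
            toks.extend([f"[{scar}]", gate])
        toks.append(f"[{self.closing_scar}]")
        return "--".join(toks) + "\n"


def layout(assignment: Assignment, library: GateLibrary) -> LayoutPlan:
    """Order assigned gates by the enforced family order and attach scars.

    The first scar is always "A" and the last "C"; intermediate scars are
    drawn from the declared scar order as needed.
    """
    gnames = sorted(set(assignment.node_to_gate.values()))
    if not gnames:
        raise AssignmentError("cannot lay out an empty assignment")
    order = list(library.layout.gate_order)
    ranked = []
    for gname in gnames:
        fam = library.gate(gname).repressor_family
        if fam not in order:
            raise ValidationError(
                f"repressor family {fam!r} (gate {gname}) is missing from "
                "the enforced gate order")
        ranked.append((order.index(fam), gname))
    ranked.sort()
    scars = list(library.layout.scar_order)
    middle = scars[1:-1]
    if len(ranked) - 1 > len(middle):
        raise ValidationError(
            f"{len(ranked)} gates need {len(ranked) - 1} internal scars but "
            f"only {len(middle)} are defined")
    entries = []
    for i, (_, gname) in enumerate(ranked):
        scar = scars[0] if i == 0 else middle[i - 1]
        entries.append((scar, gname))
    return LayoutPlan(entries=tuple(entries), closing_scar=scars[-1])
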