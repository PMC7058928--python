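"""Shared fixtures: the packaged library, randomized small circuits, and
an independent recursive evaluator used as an oracle for the topological
steady-state solver."""

from __future__ import annotations

import random

import pytest

import norcad
from norcad import (Assignment, CircuitNetlist, Node, builtin_library,
                    design, seven_segment_spec)
from norcad.steady_state import INPUT, NOR2, NOT, OUTPUT


@pytest.fixture(scope="session")
def library():
    return builtin_library()


@pytest.fixture(scope="session")
def segment_designs(library):
    """All seven display-segment circuits designed once per session."""
    out = {}
    for seg in norcad.SEGMENTS:
        spec = seven_segment_spec(seg)
        out[seg] = design(spec, library, seed=1,
                          sensors=norcad.DISPLAY_SENSORS)
    return out


# --------------------------------------------------------------------------
# Randomized small circuits
# --------------------------------------------------------------------------

def random_circuit(rng: random.Random, library,
                   n_inputs: int | None = None
                   ) -> tuple[CircuitNetlist, Assignment]:
    """A random valid netlist (1-3 inputs, 1-4 logic nodes) with a random
    feasible gate assignment."""
    if n_inputs is None:
        n_inputs = rng.randint(1, 3)
    sensors = [s.name for s in library.sensors[:n_inputs]]
    nodes = [Node(name=f"x{i + 1}", kind=INPUT, sensor=sensors[i])
             for i in range(n_inputs)]
    signals = [nd.name for nd in nodes]
    n_logic = rng.randint(1, 4)
    for j in range(n_logic):
        if len(signals) >= 2 and rng.random() < 0.6:
            a, b = rng.sample(signals, 2)
            nodes.append(Node(name=f"g{j + 1}", kind=NOR2, parents=(a, b)))
        else:
            a = rng.choice(signals)
            nodes.append(Node(name=f"g{j + 1}", kind=NOT, parents=(a,)))
        signals.append(f"g{j + 1}")
    logic = [nd.name for nd in nodes if nd.kind != INPUT]
    if len(logic) >= 2 and rng.random() < 0.5:
        drivers = tuple(rng.sample(logic, 2))
    else:
        drivers = (rng.choice(logic),)
    nodes.append(Node(name="y", kind=OUTPUT, parents=drivers))
    netlist = CircuitNetlist(nodes=tuple(nodes))

    byfam = library.gates_by_family()
    fams = rng.sample(sorted(byfam), len(logic))
    gates = {node: rng.choice(sorted(g.name for g in byfam[f]))
             for node, f in zip(logic, fams)}
    return netlist, Assignment(node_to_gate=gates)


# --------------------------------------------------------------------------
# Independent recursive evaluator (oracle)
# --------------------------------------------------------------------------

def recursive_reference_fluxes(netlist, assignment, library, bits,
                               model="interference"):
    """Steady-state fluxes computed by direct recursion from the formulas,
    independently of the package's topological evaluator."""
    inputs = netlist.inputs
    bit_of = {nd.name: int(b) for nd, b in zip(inputs, bits)}
    memo: dict[str, float] = {}

    def occupancy(name: str) -> float:
        nd = netlist.node(name)
        if nd.kind == INPUT:
            s = library.sensor(assignment.sensor_for(nd))
            if s.mode == "activator-based":
                return s.alpha
            return s.alpha if bit_of[name] else s.alpha * s.beta
        g = library.gate(assignment.gate_for(nd))
        x = total_input(name)
        kn = g.K ** g.n
        xn = x ** g.n
        return g.alpha * (kn + g.beta * xn) / (kn + xn)

    def total_input(name: str) -> float:
        nd = netlist.node(name)
        if len(nd.parents) == 1:
            return flux(nd.parents[0])
        up, down = nd.parents
        f = occupancy(down) if model == "interference" else 1.0
        return f * flux(up) + flux(down)

    def flux(name: str) -> float:
        if name in memo:
            return memo[name]
        nd = netlist.node(name)
        if nd.kind == INPUT:
            s = library.sensor(assignment.sensor_for(nd))
            val = s.on_rpu if bit_of[name] else s.off_rpu
        elif nd.kind == OUTPUT:
            val = total_input(name)
        else:
            g = library.gate(assignment.gate_for(nd))
            x = total_input(name)
            kn = g.K ** g.n
            val = g.y_min + (g.y_max - g.y_min) * kn / (kn + x ** g.n)
        memo[name] = val
        return val

    return {nd.name: flux(nd.name) for nd in netlist.nodes}
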