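"""Steady-state circuit prediction.

The signal carrier throughout is RNA-polymerase flux in relative promoter
units (RPU).  A NOT/NOR gate is a repressor cassette: its input promoter(s)
drive repressor expression, and the repressor shuts off the gate's output
promoter.  The response of gate *i* to a total input flux *x* is the
declining Hill function

    y_i(x) = y_min + (y_max - y_min) * K^n / (K^n + x^n).

A NOR gate has two input promoters *in tandem* on the same DNA.  The naive
composition adds their fluxes, ``x = x1 + x2``.  In reality the downstream
promoter (position 2) interferes with the upstream one (position 1): a
repressor bound at the downstream promoter roadblocks RNAP elongating from
the upstream promoter, and the downstream promoter region also suppresses
the upstream flux non-specifically.  The corrected upstream contribution is

    x = alpha * (K^n + beta * x2^n) / (K^n + x2^n) * x1 + x2,

where alpha (non-specific interference), beta (roadblocking) and the Hill
parameters K, n all belong to the *downstream* driver's gate, and x2 is
that gate's own total input (which sets its repressor occupancy).  With
alpha = beta = 1 the bracket is identically 1 and the additive model is
recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import (AssignmentError, SpecificationError,
                     StructuralError)
from .gate_library import GateLibrary, GateRecord, SensorRecord

__all__ = [
    "Node", "CircuitNetlist", "NodeState", "CircuitState", "StateRow",
    "StateTable", "Assignment",
    "hill_response", "roadblock_factor", "sensor_occupancy",
    "compose_tandem", "evaluate_state", "truth_table_prediction",
    "circuit_score", "boolean_outputs",
]

ADDITIVE = "additive"
INTERFERENCE = "interference"

INPUT, NOT, NOR2, OUTPUT = "INPUT", "NOT", "NOR2", "OUTPUT"


# --------------------------------------------------------------------------
# Netlist
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Node:
    """One netlist node.

    ``parents`` is ordered; for NOR2 and two-driver OUTPUT nodes the first
    entry is the upstream tandem position (position 1) and the second the
    downstream position (position 2).
    """

    name: str
    kind: str
    parents: tuple[str, ...] = ()
    sensor: str | None = None


_ARITY = {INPUT: (0, 0), NOT: (1, 1), NOR2: (2, 2), OUTPUT: (1, 2)}


@dataclass(frozen=True, eq=False)
class CircuitNetlist:
    """An acyclic wiring diagram of INPUT / NOT / NOR2 nodes plus OUTPUT.

    Input nodes are ordered: the first input node is input 1 and maps to
    the least-significant bit of the state index.  Equality is structural:
    the internal storage order of logic nodes is irrelevant, the input
    order is not (it carries bit significance).
    """

    nodes: tuple[Node, ...]

    def __post_init__(self):
        self.validate()

    def __eq__(self, other):
        if not isinstance(other, CircuitNetlist):
            return NotImplemented
        return (self.inputs == other.inputs
                and frozenset(self.nodes) == frozenset(other.nodes))

    def __hash__(self):
        return hash((self.inputs, frozenset(self.nodes)))

    # -- lookups ----------------------------------------------------------
    def node(self, name: str) -> Node:
        for nd in self.nodes:
            if nd.name == name:
                return nd
        raise KeyError(f"no node named {name!r}")

    @property
    def inputs(self) -> tuple[Node, ...]:
        return tuple(nd for nd in self.nodes if nd.kind == INPUT)

    @property
    def output(self) -> Node:
        outs = [nd for nd in self.nodes if nd.kind == OUTPUT]
        if len(outs) != 1:
            raise StructuralError(
                f"netlist must have exactly one OUTPUT node (found "
                f"{len(outs)})")
        return outs[0]

    @property
    def logic_nodes(self) -> tuple[Node, ...]:
        return tuple(nd for nd in self.nodes if nd.kind in (NOT, NOR2))

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        names = [nd.name for nd in self.nodes]
        if len(set(names)) != len(names):
            raise StructuralError("duplicate node names in netlist")
        byname = {nd.name: nd for nd in self.nodes}
        for nd in self.nodes:
            if nd.kind not in _ARITY:
                raise StructuralError(
                    f"node {nd.name!r}: unknown kind {nd.kind!r}")
            lo, hi = _ARITY[nd.kind]
            if not (lo <= len(nd.parents) <= hi):
                raise StructuralError(
                    f"node {nd.name!r} ({nd.kind}) has {len(nd.parents)} "
                    f"parent(s); expected between {lo} and {hi}")
            if nd.kind == NOR2 and len(set(nd.parents)) != 2:
                raise StructuralError(
                    f"NOR2 node {nd.name!r} must have two distinct parents")
            if nd.kind == INPUT and not nd.sensor:
                raise StructuralError(
                    f"INPUT node {nd.name!r} lacks a sensor binding")
            for p in nd.parents:
                if p not in byname:
                    raise StructuralError(
                        f"node {nd.name!r} references unknown parent {p!r}")
                if byname[p].kind == OUTPUT:
                    raise StructuralError(
                        f"node {nd.name!r} cannot consume the OUTPUT node")
        self.output  # exactly one
        order = self.topological_order()  # raises on cycles
        # every non-INPUT node reachable from some INPUT
        reach = {nd.name for nd in self.inputs}
        for name in order:
            nd = byname[name]
            if nd.kind != INPUT and any(p in reach for p in nd.parents):
                reach.add(name)
        for nd in self.nodes:
            if nd.kind != INPUT and nd.name not in reach:
                raise StructuralError(
                    f"node {nd.name!r} is not reachable from any input")

    def topological_order(self) -> list[str]:
        """Kahn's algorithm with lexicographic tie-breaking (deterministic)."""
        byname = {nd.name: nd for nd in self.nodes}
        indeg = {nd.name: len(nd.parents) for nd in self.nodes}
        children: dict[str, list[str]] = {nd.name: [] for nd in self.nodes}
        for nd in self.nodes:
            for p in nd.parents:
                children[p].append(nd.name)
        ready = sorted(n for n, d in indeg.items() if d == 0)
        order: list[str] = []
        while ready:
            name = ready.pop(0)
            order.append(name)
            newly = []
            for c in children[name]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    newly.append(c)
            ready = sorted(ready + newly)
        if len(order) != len(self.nodes):
            raise StructuralError("netlist contains a cycle")
        return order


# --------------------------------------------------------------------------
# Assignment (data carrier; optimization lives in norcad.assignment)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Assignment:
    """Maps netlist logic nodes to library gate names (and inputs to
    sensors; when ``sensor_binding`` is empty the netlist's own sensor
    annotations are used)."""

    node_to_gate: Mapping[str, str]
    sensor_binding: Mapping[str, str] = field(default_factory=dict)

    def gate_for(self, node: Node) -> str:
        try:
            return self.node_to_gate[node.name]
        except KeyError:
            raise AssignmentError(f"node {node.name!r} has no assigned gate")

    def sensor_for(self, node: Node) -> str:
        if node.name in self.sensor_binding:
            return self.sensor_binding[node.name]
        if node.sensor:
            return node.sensor
        raise AssignmentError(f"input node {node.name!r} has no sensor")


# --------------------------------------------------------------------------
# Elementary responses
# --------------------------------------------------------------------------

def hill_response(gate: GateRecord, x: float) -> float:
    """Declining Hill response of a repressor gate to input flux ``x`` (RPU)."""
    if x < 0:
        raise ValueError(f"input flux must be non-negative (got {x})")
    kn = gate.K ** gate.n
    xn = x ** gate.n
    # written so the x = 0 limit is exactly y_max
    return gate.y_max - (gate.y_max - gate.y_min) * xn / (kn + xn)


def roadblock_factor(gate: GateRecord, x_down: float) -> float:
    """Interference factor exerted by a gate's output promoter sitting in
    the downstream tandem position, given that gate's own input ``x_down``.

    Returns ``alpha * (K^n + beta * x_down^n) / (K^n + x_down^n)``, which
    decreases from ``alpha`` (repressor unbound) to ``alpha * beta``
    (repressor fully bound) as ``x_down`` grows.
    """
    if x_down < 0:
        raise ValueError(f"input flux must be non-negative (got {x_down})")
    kn = gate.K ** gate.n
    xn = x_down ** gate.n
    return gate.alpha * (kn + gate.beta * xn) / (kn + xn)


def sensor_occupancy(sensor: SensorRecord, on: bool) -> float:
    """Interference factor for a sensor promoter in the downstream position.

    Sensors are two-state, so the Hill bracket collapses to its limits:
    a repressor-based sensor (e.g. LacI, TetR) has its repressor cleared
    when induced (factor ``alpha``) and bound when uninduced (``alpha *
    beta``); an activator-based sensor has no repressor to roadblock with
    and contributes ``alpha`` in either state.
    """
    if sensor.mode == "activator-based":
        return sensor.alpha
    return sensor.alpha if on else sensor.alpha * sensor.beta


def compose_tandem(y_upstream_raw: float, factor: float,
                   y_downstream: float) -> float:
    """Total flux delivered by a tandem promoter pair.

    ``factor`` is the downstream driver's interference factor (1 under the
    additive model), applied to the upstream promoter's raw flux.
    """
    if y_upstream_raw < 0 or y_downstream < 0:
        raise ValueError("promoter fluxes must be non-negative")
    if not (0 < factor <= 1):
        raise ValueError(f"interference factor must lie in (0, 1] "
                         f"(got {factor})")
    return factor * y_upstream_raw + y_downstream


# --------------------------------------------------------------------------
# Whole-circuit evaluation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeState:
    """Steady state of one node: total input flux ``x``, output flux ``y``,
    and the interference factor this node would exert if placed in a
    downstream tandem position."""

    total_input: float
    output_flux: float
    occupancy_factor: float


@dataclass(frozen=True)
class CircuitState:
    input_bits: tuple[int, ...]
    model: str
    states: Mapping[str, NodeState]
    output_flux: float


def _check_model(model: str) -> None:
    if model not in (ADDITIVE, INTERFERENCE):
        raise ValueError(f"model must be {ADDITIVE!r} or {INTERFERENCE!r} "
                         f"(got {model!r})")


def evaluate_state(netlist: CircuitNetlist, assignment: Assignment,
                   library: GateLibrary, input_bits: Sequence[int],
                   model: str = INTERFERENCE) -> CircuitState:
    """Evaluate all node steady states for one input condition.

    ``input_bits[i]`` is the state of input i+1 (the i-th INPUT node).
    """
    _check_model(model)
    inputs = netlist.inputs
    if len(input_bits) != len(inputs):
        raise ValueError(f"expected {len(inputs)} input bits, got "
                         f"{len(input_bits)}")
    bit_of = {nd.name: int(b) for nd, b in zip(inputs, input_bits)}

    states: dict[str, NodeState] = {}

    def tandem_input(node: Node) -> float:
        """Total input flux delivered by a node's 1-2 ordered drivers."""
        if len(node.parents) == 1:
            return states[node.parents[0]].output_flux
        up, down = node.parents
        factor = states[down].occupancy_factor if model == INTERFERENCE \
            else 1.0
        return compose_tandem(states[up].output_flux, factor,
                              states[down].output_flux)

    output_flux = 0.0
    for name in netlist.topological_order():
        nd = netlist.node(name)
        if nd.kind == INPUT:
            sensor = library.sensor(assignment.sensor_for(nd))
            on = bool(bit_of[name])
            flux = sensor.on_rpu if on else sensor.off_rpu
            states[name] = NodeState(total_input=0.0, output_flux=flux,
                                     occupancy_factor=sensor_occupancy(
                                         sensor, on))
        elif nd.kind in (NOT, NOR2):
            gate = library.gate(assignment.gate_for(nd))
            x = tandem_input(nd)
            states[name] = NodeState(
                total_input=x,
                output_flux=hill_response(gate, x),
                occupancy_factor=roadblock_factor(gate, x))
        else:  # OUTPUT
            x = tandem_input(nd)
            states[name] = NodeState(total_input=x, output_flux=x,
                                     occupancy_factor=1.0)
            output_flux = x
    return CircuitState(input_bits=tuple(int(b) for b in input_bits),
                        model=model, states=states, output_flux=output_flux)


# --------------------------------------------------------------------------
# Truth tables over all input conditions
# --------------------------------------------------------------------------

def boolean_outputs(netlist: CircuitNetlist) -> list[int]:
    """Exact Boolean semantics of the netlist, one output bit per input
    bit-vector in canonical order (input 1 = least-significant bit)."""
    n = netlist.n_inputs
    out = []
    for k in range(2 ** n):
        bits = {nd.name: (k >> i) & 1
                for i, nd in enumerate(netlist.inputs)}
        val: dict[str, int] = {}
        for name in netlist.topological_order():
            nd = netlist.node(name)
            if nd.kind == INPUT:
                val[name] = bits[name]
            elif nd.kind == NOT:
                val[name] = 1 - val[nd.parents[0]]
            elif nd.kind == NOR2:
                val[name] = 1 - (val[nd.parents[0]] | val[nd.parents[1]])
            else:  # OUTPUT: tandem = OR of drivers
                val[name] = max(val[p] for p in nd.parents)
        out.append(val[netlist.output.name])
    return out


@dataclass(frozen=True)
class StateRow:
    input_bits: tuple[int, ...]
    state: CircuitState
    output_flux: float
    required: str  # "ON", "OFF", or "X" (don't care)


@dataclass(frozen=True)
class StateTable:
    rows: tuple[StateRow, ...]

    def to_tsv(self) -> str:
        lines = ["bits\toutput_rpu\trequired"]
        for row in self.rows:
            bits = "".join(str(b) for b in reversed(row.input_bits))
            lines.append(f"{bits}\t{row.output_flux:.6g}\t{row.required}")
        return "\n".join(lines) + "\n"


def truth_table_prediction(netlist: CircuitNetlist, assignment: Assignment,
                           library: GateLibrary,
                           model: str = INTERFERENCE,
                           spec=None) -> StateTable:
    """Predict output flux for every input bit-vector.

    Rows follow canonical binary order: row k has input i set to bit i-1 of
    k (input 1 is the least-significant bit).  Required logic levels come
    from ``spec`` (a TruthSpec with don't-cares) when given, otherwise from
    the netlist's own Boolean semantics.
    """
    n = netlist.n_inputs
    if spec is not None:
        required = list(spec.outputs)
        if len(required) != 2 ** n:
            raise SpecificationError(
                f"truth spec has {len(required)} rows; netlist expects "
                f"{2 ** n}")
    else:
        required = ["ON" if b else "OFF" for b in boolean_outputs(netlist)]
    rows = []
    for k in range(2 ** n):
        bits = tuple((k >> i) & 1 for i in range(n))
        st = evaluate_state(netlist, assignment, library, bits, model)
        rows.append(StateRow(input_bits=bits, state=st,
                             output_flux=st.output_flux,
                             required=required[k]))
    return StateTable(rows=tuple(rows))


def circuit_score(table: StateTable) -> float:
    """Separation score: min flux over required-ON rows divided by max flux
    over required-OFF rows.  Greater than 1 means the worst ON state still
    clears the worst OFF state; don't-care rows are ignored."""
    on = [r.output_flux for r in table.rows if r.required == "ON"]
    off = [r.output_flux for r in table.rows if r.required == "OFF"]
    if not on or not off:
        raise SpecificationError(
            "scoring requires at least one required-ON and one required-OFF "
            "row")
    return min(on) / max(off)
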