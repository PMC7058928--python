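"""Truth-table to NOT/NOR2 netlist synthesis.

The hardware basis mirrors the wet-ware primitives: NOT gates (one input
promoter), NOR2 gates (two input promoters in tandem; fan-in is capped at
two because a gate cassette carries at most two promoters), and a free
2-input OR at the output stage (two output promoters placed in tandem in
front of the reporter).

Two synthesis modes are provided:

``enumerate``
    Exhaustive iterative-deepening search over gate counts; returns a
    provably minimal realization.  Practical for small specifications.

``minimize``
    Algebraic pre-simplification (Quine-McCluskey with don't-cares, both
    sum-of-products and product-of-sums, for the function and its
    complement) followed by polarity-aware technology mapping onto the
    NOT/NOR2 basis with structural sharing.  Fast, deterministic,
    near-minimal; used for the 4-input display circuits.

Don't-care rows are exploited in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import sympy
from sympy.logic import SOPform, POSform

from .errors import CapacityError, FormatError, SpecificationError
from .steady_state import (INPUT, NOR2, NOT, OUTPUT, CircuitNetlist, Node,
                           boolean_outputs)

__all__ = [
    "TruthSpec", "synthesize", "netlist_truth_table",
    "parse_netlist", "write_netlist", "netlist_to_text",
]

ON, OFF, DC = "ON", "OFF", "X"


# --------------------------------------------------------------------------
# Truth specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthSpec:
    """Required output level per input bit-vector.

    ``outputs[k]`` is the level ("ON", "OFF" or "X" for don't-care)
    required when the inputs spell the integer k, with input 1 as the
    least-significant bit.
    """

    n_inputs: int
    outputs: tuple[str, ...]

    def __post_init__(self):
        if not (1 <= self.n_inputs <= 4):
            raise SpecificationError(
                f"n_inputs must be between 1 and 4 (got {self.n_inputs})")
        if len(self.outputs) != 2 ** self.n_inputs:
            raise SpecificationError(
                f"expected {2 ** self.n_inputs} output rows, got "
                f"{len(self.outputs)}")
        bad = sorted({o for o in self.outputs if o not in (ON, OFF, DC)})
        if bad:
            raise SpecificationError(f"unknown output levels: {bad}")
        if ON not in self.outputs or OFF not in self.outputs:
            raise SpecificationError(
                "spec needs at least one required-ON and one required-OFF "
                "row")

    @classmethod
    def from_bits(cls, n_inputs: int, rows: Sequence[str | int]) -> "TruthSpec":
        conv = {"1": ON, "0": OFF, "X": DC, "x": DC, 1: ON, 0: OFF}
        return cls(n_inputs, tuple(conv[r] for r in rows))

    # bitmask views (bit k of the mask = row k)
    @property
    def on_mask(self) -> int:
        return sum(1 << k for k, o in enumerate(self.outputs) if o == ON)

    @property
    def care_mask(self) -> int:
        return sum(1 << k for k, o in enumerate(self.outputs) if o != DC)

    def matches(self, signal_mask: int) -> bool:
        return (signal_mask & self.care_mask) == self.on_mask

    def to_tsv(self) -> str:
        conv = {ON: "1", OFF: "0", DC: "X"}
        lines = []
        for k, o in enumerate(self.outputs):
            bits = format(k, f"0{self.n_inputs}b")  # MSB first
            lines.append(f"{bits}\t{conv[o]}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "TruthSpec":
        rows: dict[int, str] = {}
        n = None
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 'bits<TAB>0|1|X'")
            bits, level = parts
            if n is None:
                n = len(bits)
            if len(bits) != n or any(c not in "01" for c in bits):
                raise FormatError(f"line {lineno}: bad bit-vector {bits!r}")
            rows[int(bits, 2)] = {"0": OFF, "1": ON, "X": DC,
                                  "x": DC}.get(level)
            if rows[int(bits, 2)] is None:
                raise FormatError(f"line {lineno}: bad level {level!r}")
        if n is None:
            raise FormatError("empty truth-table file")
        if set(rows) != set(range(2 ** n)):
            raise FormatError("truth-table file must cover every bit-vector "
                              "exactly once")
        return cls(n, tuple(rows[k] for k in range(2 ** n)))


def netlist_truth_table(netlist: CircuitNetlist) -> TruthSpec:
    """Exact Boolean semantics of a netlist as a (don't-care-free) spec."""
    return TruthSpec(netlist.n_inputs,
                     tuple(ON if b else OFF
                           for b in boolean_outputs(netlist)))


# --------------------------------------------------------------------------
# Netlist construction helpers
# --------------------------------------------------------------------------

def _input_masks(n: int) -> list[int]:
    return [sum(1 << k for k in range(2 ** n) if (k >> i) & 1)
            for i in range(n)]


class _Chain:
    """A growing NOT/NOR2 netlist with structural sharing by truth mask."""

    def __init__(self, n_inputs: int, sensors: Sequence[str]):
        self.n = n_inputs
        self.full = (1 << (2 ** n_inputs)) - 1
        self.sensors = list(sensors)
        self.names: list[str] = [f"x{i + 1}" for i in range(n_inputs)]
        self.masks: list[int] = _input_masks(n_inputs)
        self.depth: list[int] = [0] * n_inputs
        self.kinds: list[tuple] = [(INPUT, ())] * n_inputs
        self.cache: dict[int, int] = {m: i for i, m in enumerate(self.masks)}

    @property
    def n_gates(self) -> int:
        return len(self.names) - self.n

    def lookup(self, mask: int) -> int | None:
        return self.cache.get(mask)

    def add(self, kind: str, ops: tuple[int, ...]) -> int:
        if kind == NOT:
            mask = self.full & ~self.masks[ops[0]]
        else:
            mask = self.full & ~(self.masks[ops[0]] | self.masks[ops[1]])
        hit = self.cache.get(mask)
        if hit is not None:
            return hit
        idx = len(self.names)
        self.names.append(f"g{self.n_gates + 1}")
        self.masks.append(mask)
        self.depth.append(1 + max(self.depth[o] for o in ops))
        self.kinds.append((kind, ops))
        self.cache[mask] = idx
        return idx

    def not_of(self, op: int) -> int:
        return self.add(NOT, (op,))

    def nor_of(self, a: int, b: int) -> int:
        if a == b:  # NOR(a, a) degenerates to NOT(a)
            return self.add(NOT, (a,))
        return self.add(NOR2, (a, b))

    def to_netlist(self, drivers: Sequence[int]) -> CircuitNetlist:
        """Emit the cone of the given output drivers as a CircuitNetlist.

        Tandem slot convention: the lexicographically smaller operand name
        goes to position 1 (upstream)."""
        needed = set()
        stack = list(drivers)
        while stack:
            idx = stack.pop()
            if idx in needed:
                continue
            needed.add(idx)
            stack.extend(self.kinds[idx][1])
        nodes = [Node(name=f"x{i + 1}", kind=INPUT,
                      sensor=self.sensors[i]) for i in range(self.n)]
        # rename kept gates in chain order for a canonical result
        kept = [i for i in range(self.n, len(self.names)) if i in needed]
        newname = {i: self.names[i] for i in range(self.n)}
        for j, i in enumerate(kept):
            newname[i] = f"g{j + 1}"
        for i in kept:
            kind, ops = self.kinds[i]
            parents = tuple(sorted(newname[o] for o in ops))
            nodes.append(Node(name=newname[i], kind=kind, parents=parents))
        dnames = tuple(sorted(newname[d] for d in dict.fromkeys(drivers)))
        nodes.append(Node(name="y", kind=OUTPUT, parents=dnames))
        return CircuitNetlist(nodes=tuple(nodes))


def _count_not(netlist: CircuitNetlist) -> int:
    return sum(1 for nd in netlist.nodes if nd.kind == NOT)


def _netlist_depth(netlist: CircuitNetlist) -> int:
    depth: dict[str, int] = {}
    for name in netlist.topological_order():
        nd = netlist.node(name)
        if nd.kind == INPUT:
            depth[name] = 0
        else:
            depth[name] = (0 if nd.kind == OUTPUT else 1) + \
                max(depth[p] for p in nd.parents)
    return depth[netlist.output.name]


def _rank_key(netlist: CircuitNetlist) -> tuple:
    # ties among equal-size realizations break toward shallower circuits
    # (fewer layers = faster response), then fewer NOT nodes, then the
    # lexicographically smallest canonical text
    return (len(netlist.logic_nodes), _netlist_depth(netlist),
            _count_not(netlist), netlist_to_text(netlist))


# --------------------------------------------------------------------------
# Exhaustive enumeration (exact minimal)
# --------------------------------------------------------------------------

def _enumerate_search(spec: TruthSpec, max_gates: int,
                      sensors: Sequence[str]) -> CircuitNetlist:
    n = spec.n_inputs

    def solutions_using_last(chain: _Chain, require_last: bool):
        """Yield driver tuples compatible with the spec."""
        sigs = range(len(chain.names))
        last = len(chain.names) - 1
        for i in sigs:
            if require_last and i != last:
                continue
            if spec.matches(chain.masks[i]):
                yield (i,)
        for i in sigs:
            for j in sigs:
                if j <= i:
                    continue
                if require_last and last not in (i, j):
                    continue
                if spec.matches(chain.masks[i] | chain.masks[j]):
                    yield (i, j)

    best: CircuitNetlist | None = None
    best_key: tuple | None = None

    def dfs(chain: _Chain, remaining: int):
        nonlocal best, best_key
        if remaining == 0:
            for drivers in solutions_using_last(chain,
                                                require_last=chain.n_gates > 0):
                net = chain.to_netlist(drivers)
                key = _rank_key(net)
                if best_key is None or key < best_key:
                    best, best_key = net, key
            return
        s = len(chain.names)
        for i in range(s):
            mask = chain.full & ~chain.masks[i]
            if mask in chain.cache:
                continue
            sub = _copy_chain(chain)
            sub.not_of(i)
            dfs(sub, remaining - 1)
        for i in range(s):
            for j in range(i + 1, s):
                mask = chain.full & ~(chain.masks[i] | chain.masks[j])
                if mask in chain.cache:
                    continue
                sub = _copy_chain(chain)
                sub.nor_of(i, j)
                dfs(sub, remaining - 1)

    for m in range(0, max_gates + 1):
        best, best_key = None, None
        dfs(_Chain(n, sensors), m)
        if best is not None:
            return best
    raise CapacityError(
        f"no NOT/NOR2 realization of the specification found within "
        f"{max_gates} gate(s); every circuit of up to {max_gates} gates "
        "was explored")


def _copy_chain(chain: _Chain) -> _Chain:
    sub = _Chain.__new__(_Chain)
    sub.n = chain.n
    sub.full = chain.full
    sub.sensors = chain.sensors
    sub.names = list(chain.names)
    sub.masks = list(chain.masks)
    sub.depth = list(chain.depth)
    sub.kinds = list(chain.kinds)
    sub.cache = dict(chain.cache)
    return sub


# --------------------------------------------------------------------------
# Algebraic minimization + technology mapping
# --------------------------------------------------------------------------

def _mask_of_expr(e, symbols, n: int) -> int:
    mask = 0
    for k in range(2 ** n):
        env = {symbols[i]: bool((k >> i) & 1) for i in range(n)}
        if bool(e.subs(env)):
            mask |= 1 << k
    return mask


class _Mapper:
    """Maps a sympy boolean expression onto a _Chain, polarity-aware."""

    def __init__(self, chain: _Chain, symbols):
        self.chain = chain
        self.symbols = symbols
        self.index = {s: i for i, s in enumerate(symbols)}

    def _ordered(self, args):
        n = self.chain.n
        return sorted(args, key=lambda a: _mask_of_expr(a, self.symbols, n))

    def build(self, e, neg: bool) -> int:
        """Return the chain signal computing ``e`` (or its complement)."""
        if e is sympy.true or e is sympy.false:
            raise SpecificationError("cannot realize a constant function "
                                     "in promoter hardware")
        if isinstance(e, sympy.Symbol):
            idx = self.index[e]
            return self.chain.not_of(idx) if neg else idx
        if isinstance(e, sympy.Not):
            return self.build(e.args[0], not neg)
        if isinstance(e, sympy.Or):
            args = self._ordered(e.args)
            return self.nor_list(args) if neg else self.or_list(args)
        if isinstance(e, sympy.And):
            comp = self._ordered([sympy.Not(a) for a in e.args])
            return self.or_list(comp) if neg else self.nor_list(comp)
        raise TypeError(f"unsupported boolean operator: {type(e).__name__}")

    def or_list(self, args) -> int:
        if len(args) == 1:
            return self.build(args[0], False)
        return self.chain.not_of(self.nor_list(args))

    def nor_list(self, args) -> int:
        """Signal computing NOT(OR(args))."""
        if len(args) == 1:
            return self.build(args[0], True)
        half = (len(args) + 1) // 2
        a = self.or_list(args[:half])
        b = self.or_list(args[half:])
        return self.chain.nor_of(a, b)

    def top(self, e) -> tuple[int, ...]:
        """Output drivers for ``e``, using the free tandem OR when the top
        operator is an OR."""
        if isinstance(e, sympy.Or):
            args = self._ordered(e.args)
            half = (len(args) + 1) // 2
            return (self.or_list(args[:half]), self.or_list(args[half:]))
        return (self.build(e, False),)


_CONST0, _CONST1 = "const0", "const1"


class _Shannon:
    """Recursive Shannon-cofactor mapper working directly on
    (on-mask, care-mask) targets.

    F = ITE(v, f1, f0) = OR(NOR(v', NOT f1), NOR(v, NOT f0)); the top-level
    OR is absorbed by the free tandem output stage.  Cofactoring turns the
    off-half of each branch into don't-cares, so previously built signals
    are frequently reusable ("compatible": agreeing with the target on
    every care row).
    """

    def __init__(self, chain: _Chain, var_order: Sequence[int],
                 modes: Sequence[str] = ()):
        self.chain = chain
        self.var_order = list(var_order)
        # expansion style per recursion depth: "or" uses the sum form
        # OR(AND(v, f1), AND(v', f0)); "and" the product form
        # AND(OR(v, f0), OR(v', f1)) realized as a single NOR of NORs
        self.modes = list(modes) or ["or"] * len(var_order)
        n = chain.n
        self.vmasks = _input_masks(n)

    def _compatible(self, on: int, care: int) -> int | None:
        for i, m in enumerate(self.chain.masks):
            if (m & care) == (on & care):
                return i
        return None

    def build(self, on: int, care: int, neg: bool, depth: int = 0):
        """Return a signal index compatible with the target (complemented
        when ``neg``), or a constant marker."""
        if neg:
            on = care & ~on
        if care & on == 0:
            return _CONST0
        if care & ~on == 0:
            return _CONST1
        hit = self._compatible(on, care)
        if hit is not None:
            return hit
        if self.modes[depth] == "and":
            built = self._build_product(on, care, depth)
            if built is not None:
                return built
        t1, t2 = self.terms(on, care, depth)
        if t1 is None and t2 is None:
            return _CONST0
        if t1 is None:
            return t2
        if t2 is None:
            return t1
        return self.chain.not_of(self.chain.nor_of(t1, t2))

    def _build_product(self, on: int, care: int, depth: int) -> int | None:
        """Product-form expansion AND(OR(v, f0), OR(v', f1)) as
        NOR(NOR(v, f0), NOR(v', f1)); falls back (returns None) when a
        cofactor is constant."""
        v = self.var_order[depth]
        vm = self.vmasks[v]
        f1 = self.build(on & vm, care & vm, neg=False, depth=depth + 1)
        f0 = self.build(on & ~vm, care & ~vm, neg=False, depth=depth + 1)
        if f1 in (_CONST0, _CONST1) or f0 in (_CONST0, _CONST1):
            return None
        u1 = self.chain.nor_of(v, f0)
        u2 = self.chain.nor_of(self.chain.not_of(v), f1)
        return self.chain.nor_of(u1, u2)

    def terms(self, on: int, care: int, depth: int = 0):
        """The two AND terms of the Shannon expansion (either may be None
        when its cofactor is constant-0); their OR realizes the target."""
        v = self.var_order[depth]
        vm = self.vmasks[v]
        f1c = self.build(on & vm, care & vm, neg=True, depth=depth + 1)
        f0c = self.build(on & ~vm, care & ~vm, neg=True, depth=depth + 1)
        # term1 = AND(v, f1) = NOR(v', NOT f1)
        if f1c == _CONST1:        # f1 == 0
            t1 = None
        elif f1c == _CONST0:      # f1 == 1 -> term is v itself
            t1 = v
        else:
            t1 = self.chain.nor_of(self.chain.not_of(v), f1c)
        # term2 = AND(v', f0) = NOR(v, NOT f0)
        if f0c == _CONST1:
            t2 = None
        elif f0c == _CONST0:
            t2 = self.chain.not_of(v)
        else:
            t2 = self.chain.nor_of(v, f0c)
        return t1, t2


def _minimize_search(spec: TruthSpec, max_gates: int,
                     sensors: Sequence[str]) -> CircuitNetlist:
    n = spec.n_inputs
    symbols = sympy.symbols(f"x1:{n + 1}")
    minterms = [[(k >> i) & 1 for i in range(n)]
                for k, o in enumerate(spec.outputs) if o == ON]
    maxterms = [[(k >> i) & 1 for i in range(n)]
                for k, o in enumerate(spec.outputs) if o == OFF]
    dontcares = [[(k >> i) & 1 for i in range(n)]
                 for k, o in enumerate(spec.outputs) if o == DC]

    forms = [
        SOPform(symbols, minterms, dontcares),
        POSform(symbols, minterms, dontcares),
        sympy.Not(SOPform(symbols, maxterms, dontcares)),
        sympy.Not(POSform(symbols, maxterms, dontcares)),
    ]

    candidates: list[CircuitNetlist] = []
    for form in forms:
        chain = _Chain(n, sensors)
        mapper = _Mapper(chain, symbols)
        try:
            drivers = mapper.top(form)
        except SpecificationError:
            continue
        candidates.append(chain.to_netlist(drivers))

    from itertools import permutations, product
    on, care = spec.on_mask, spec.care_mask
    for order in permutations(range(n)):
        for modes in product(("or", "and"), repeat=n):
            chain = _Chain(n, sensors)
            sh = _Shannon(chain, order, modes)
            hit = sh._compatible(on, care)
            if hit is not None:
                drivers: tuple[int, ...] = (hit,)
            elif modes[0] == "and":
                built = sh.build(on, care, neg=False)
                if built in (_CONST0, _CONST1):
                    continue
                drivers = (built,)
            else:
                t1, t2 = sh.terms(on, care)
                drivers = tuple(t for t in (t1, t2) if t is not None)
            if drivers:
                candidates.append(chain.to_netlist(drivers))

    best, best_key = None, None
    for net in candidates:
        if not spec.matches(_netlist_mask(net)):  # defensive
            continue
        key = _rank_key(net)
        if best_key is None or key < best_key:
            best, best_key = net, key
    if best is None or len(best.logic_nodes) > max_gates:
        found = 0 if best is None else len(best.logic_nodes)
        raise CapacityError(
            f"minimization produced no realization within {max_gates} "
            f"gate(s) (best found: {found})")
    return best


def _netlist_mask(netlist: CircuitNetlist) -> int:
    return sum(1 << k for k, b in enumerate(boolean_outputs(netlist)) if b)


def synthesize(spec: TruthSpec, max_gates: int = 12,
               mode: str = "minimize",
               sensors: Sequence[str] | None = None) -> CircuitNetlist:
    """Synthesize a NOT/NOR2 netlist realizing ``spec``.

    The result matches the spec on every non-don't-care row; the output
    stage may use a free 2-driver tandem OR.  Deterministic for a given
    spec.  ``sensors`` optionally names the sensor bound to each input
    (placeholders ``S1..Sn`` otherwise).
    """
    if max_gates < 1:
        raise ValueError("max_gates must be >= 1")
    if sensors is None:
        sensors = [f"S{i + 1}" for i in range(spec.n_inputs)]
    if len(sensors) != spec.n_inputs:
        raise ValueError("need one sensor name per input")
    if mode == "enumerate":
        net = _enumerate_search(spec, max_gates, sensors)
    elif mode == "minimize":
        net = _minimize_search(spec, max_gates, sensors)
    else:
        raise ValueError(f"unknown synthesis mode {mode!r}")
    assert spec.matches(_netlist_mask(net)), "synthesis produced a netlist " \
        "that violates its specification"
    return net


# --------------------------------------------------------------------------
# Netlist text format
# --------------------------------------------------------------------------
#
# Line-oriented grammar (tab- or space-separated):
#   input  <id> <sensor>
#   not    <id> <parent>
#   nor    <id> <parent_pos1> <parent_pos2>
#   output <id> <driver1> [driver2]
# Blank lines and lines starting with '#' are ignored.

def netlist_to_text(netlist: CircuitNetlist) -> str:
    lines = ["# norcad netlist"]
    order = netlist.topological_order()
    for nd in netlist.inputs:
        lines.append(f"input\t{nd.name}\t{nd.sensor}")
    for name in order:
        nd = netlist.node(name)
        if nd.kind == NOT:
            lines.append(f"not\t{nd.name}\t{nd.parents[0]}")
        elif nd.kind == NOR2:
            lines.append(f"nor\t{nd.name}\t{nd.parents[0]}\t{nd.parents[1]}")
    out = netlist.output
    lines.append("output\t" + out.name + "\t" + "\t".join(out.parents))
    return "\n".join(lines) + "\n"


def write_netlist(netlist: CircuitNetlist, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(netlist_to_text(netlist))


def parse_netlist_text(text: str) -> CircuitNetlist:
    nodes: list[Node] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        kw = parts[0].lower()
        try:
            if kw == "input" and len(parts) == 3:
                nodes.append(Node(name=parts[1], kind=INPUT,
                                  sensor=parts[2]))
            elif kw == "not" and len(parts) == 3:
                nodes.append(Node(name=parts[1], kind=NOT,
                                  parents=(parts[2],)))
            elif kw == "nor" and len(parts) == 4:
                nodes.append(Node(name=parts[1], kind=NOR2,
                                  parents=(parts[2], parts[3])))
            elif kw == "output" and len(parts) in (3, 4):
                nodes.append(Node(name=parts[1], kind=OUTPUT,
                                  parents=tuple(parts[2:])))
            else:
                raise FormatError(
                    f"line {lineno}: unrecognized netlist line {line!r}")
        except FormatError:
            raise
    return CircuitNetlist(nodes=tuple(nodes))


def parse_netlist(path) -> CircuitNetlist:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_netlist_text(fh.read())
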