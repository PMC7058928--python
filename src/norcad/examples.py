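"""Packaged worked examples: the BCD-to-7-segment decoder and the tandem
validation suite.

The display application maps a binary-coded decimal digit, conveyed by
four inducible sensors, onto the on/off states of display segments A-G.
Input order (input 1 = least-significant bit of the digit) follows the
inducer wiring: input 1 = P_Lux2 (OC6), input 2 = P_Tet (aTc), input 3 =
P_Cin (OHC14), input 4 = P_Tac (IPTG).  The segment patterns follow the
classic BCD decoder chips (SN74LS49 family), in which 6 is rendered
without segment A and 9 without segment D; rows 10-15 are don't-care by
default since only digits 0-9 are ever requested.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .dynamics import InducerSchedule
from .gate_library import GateLibrary
from .logic_synthesis import DC, OFF, ON, TruthSpec
from .steady_state import (INPUT, INTERFERENCE, NOT, OUTPUT, Assignment,
                           CircuitNetlist, Node, evaluate_state)

__all__ = [
    "SEGMENTS", "SEGMENT_ON_DIGITS", "DISPLAY_SENSORS",
    "seven_segment_spec", "digit_bits", "digit_cycle_schedule",
    "two_not_circuit", "tandem_validation_suite",
    "tandem_validation_predictions",
]

SEGMENTS = "ABCDEFG"

#: Digits (0-9) for which each display segment is lit.
SEGMENT_ON_DIGITS: dict[str, frozenset[int]] = {
    "A": frozenset({0, 2, 3, 5, 7, 8, 9}),
    "B": frozenset({0, 1, 2, 3, 4, 7, 8, 9}),
    "C": frozenset({0, 1, 3, 4, 5, 6, 7, 8, 9}),
    "D": frozenset({0, 2, 3, 5, 6, 8}),
    "E": frozenset({0, 2, 6, 8}),
    "F": frozenset({0, 4, 5, 6, 8, 9}),
    "G": frozenset({2, 3, 4, 5, 6, 8, 9}),
}

#: Sensor bound to each of the four inputs, input 1 first.
DISPLAY_SENSORS = ("P_Lux2", "P_Tet", "P_Cin", "P_Tac")


def seven_segment_spec(segment: str,
                       dont_care_high: bool = True) -> TruthSpec:
    """Truth spec for one display segment over the 4-bit digit input.

    Rows 10-15 (non-decimal codes) default to don't-care; with
    ``dont_care_high=False`` they are required OFF instead.
    """
    segment = segment.upper()
    if segment not in SEGMENT_ON_DIGITS:
        raise KeyError(f"unknown segment {segment!r}; expected one of "
                       f"{SEGMENTS}")
    on = SEGMENT_ON_DIGITS[segment]
    outputs = []
    for k in range(16):
        if k < 10:
            outputs.append(ON if k in on else OFF)
        else:
            outputs.append(DC if dont_care_high else OFF)
    return TruthSpec(4, tuple(outputs))


def digit_bits(digit: int) -> tuple[int, int, int, int]:
    """Sensor-state bits for a decimal digit (input 1 = LSB)."""
    if not 0 <= digit <= 9:
        raise ValueError(f"digit must be 0-9 (got {digit})")
    return tuple((digit >> i) & 1 for i in range(4))


def digit_cycle_schedule(segment_hours: float = 8.0) -> InducerSchedule:
    """The 88-hour display protocol: 8 h in state 0, then each digit 1-9
    for 8 h, closing with a return to 0."""
    digits = list(range(10)) + [0]
    return InducerSchedule.from_states([digit_bits(d) for d in digits],
                                       segment_hours)


# --------------------------------------------------------------------------
# Tandem (two-NOT / NAND) validation suite
# --------------------------------------------------------------------------

def two_not_circuit(gate_upstream: str, gate_downstream: str,
                    sensors: Sequence[str] = ("P_Tet", "P_Tac")
                    ) -> tuple[CircuitNetlist, Assignment]:
    """A NAND test circuit: two sensor-driven NOT gates whose output
    promoters sit in tandem (upstream/downstream) in front of the
    reporter."""
    netlist = CircuitNetlist(nodes=(
        Node(name="x1", kind=INPUT, sensor=sensors[0]),
        Node(name="x2", kind=INPUT, sensor=sensors[1]),
        Node(name="g1", kind=NOT, parents=("x1",)),
        Node(name="g2", kind=NOT, parents=("x2",)),
        Node(name="y", kind=OUTPUT, parents=("g1", "g2")),
    ))
    assignment = Assignment(node_to_gate={"g1": gate_upstream,
                                          "g2": gate_downstream})
    return netlist, assignment


def tandem_validation_suite(library: GateLibrary,
                            pool_size: int = 5) -> list[tuple[str, str]]:
    """Deterministic roster of 20 ordered NOT-gate pairs for the tandem
    suite: all ordered pairs drawn from the first ``pool_size`` gates of
    distinct repressor families in library order (5 x 4 = 20)."""
    pool: list[str] = []
    seen = set()
    for g in library.gates:
        if g.repressor_family in seen:
            continue
        seen.add(g.repressor_family)
        pool.append(g.name)
        if len(pool) == pool_size:
            break
    return [(a, b) for a in pool for b in pool if a != b]


def tandem_validation_predictions(library: GateLibrary,
                                  model: str = INTERFERENCE) -> pd.DataFrame:
    """Predicted output flux for every tandem test circuit under all four
    inducer combinations (20 circuits x 4 states = 80 predictions)."""
    rows = []
    for cid, (up, down) in enumerate(tandem_validation_suite(library), 1):
        netlist, assignment = two_not_circuit(up, down)
        for bits in ((0, 0), (1, 0), (0, 1), (1, 1)):
            st = evaluate_state(netlist, assignment, library, bits, model)
            rows.append({"circuit": cid, "upstream_gate": up,
                         "downstream_gate": down,
                         "aTc": bits[0], "IPTG": bits[1],
                         "predicted_rpu": st.output_flux})
    return pd.DataFrame(rows)
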