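"""Total RNAP flux (J_RNAP): the circuit's "power" draw on the host.

Every promoter physically present in the construct draws RNA polymerase
from the shared host pool.  Summing the instantaneous fluxes of all
promoter instances gives a state-dependent power metric: each tandem input
promoter counts separately (with the interference correction applied to
the upstream member of a pair), and the output promoter(s) driving the
reporter count as well.  Constitutively expressed sensor regulators on the
sensor plasmid are not part of the inventory.  The module reports the
metric; no safety threshold is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .dynamics import Trajectory, node_fluxes
from .errors import AssignmentError
from .gate_library import GateLibrary
from .steady_state import (INPUT, INTERFERENCE, Assignment,
                           CircuitNetlist, CircuitState)

__all__ = ["PowerReport", "PowerSeries", "state_power", "trajectory_power",
           "promoter_inventory"]


def promoter_inventory(netlist: CircuitNetlist) -> list[tuple[str, str, int]]:
    """All physical promoter instances as (driver, consumer, position)
    triples; position is 1 (upstream) or 2 (downstream) within a tandem
    pair, 0 for a lone promoter."""
    inventory = []
    for name in netlist.topological_order():
        nd = netlist.node(name)
        if nd.kind == INPUT:
            continue
        if len(nd.parents) == 1:
            inventory.append((nd.parents[0], name, 0))
        else:
            up, down = nd.parents
            inventory.append((up, name, 1))
            inventory.append((down, name, 2))
    return inventory


@dataclass(frozen=True)
class PowerReport:
    """Per-promoter flux breakdown for one circuit state."""

    entries: tuple[tuple[str, float], ...]  # (promoter label, flux RPU)

    @property
    def total(self) -> float:
        return sum(f for _, f in self.entries)

    def to_tsv(self) -> str:
        lines = ["promoter\tflux_rpu"]
        for label, flux in self.entries:
            lines.append(f"{label}\t{flux:.6g}")
        lines.append(f"TOTAL\t{self.total:.6g}")
        return "\n".join(lines) + "\n"


def _entries_from(netlist: CircuitNetlist, outputs: Mapping[str, float],
                  occ: Mapping[str, float], model: str
                  ) -> tuple[tuple[str, float], ...]:
    entries = []
    for driver, consumer, pos in promoter_inventory(netlist):
        flux = outputs[driver]
        if pos == 1 and model == INTERFERENCE:
            down = netlist.node(consumer).parents[1]
            flux *= occ[down]
        entries.append((f"{driver}@{consumer}", flux))
    return tuple(entries)


def state_power(netlist: CircuitNetlist, assignment: Assignment,
                state: CircuitState) -> PowerReport:
    """Sum RNAP flux over every promoter instance at one steady state."""
    try:
        outputs = {n: s.output_flux for n, s in state.states.items()}
        occ = {n: s.occupancy_factor for n, s in state.states.items()}
    except AttributeError as exc:
        raise AssignmentError("state_power needs evaluated node states "
                              "(see evaluate_state)") from exc
    missing = [nd.name for nd in netlist.nodes if nd.name not in outputs]
    if missing:
        raise AssignmentError(f"missing node states for: {missing}")
    return PowerReport(entries=_entries_from(netlist, outputs, occ,
                                             state.model))


@dataclass(frozen=True)
class PowerSeries:
    time: np.ndarray
    total: np.ndarray
    per_promoter: Mapping[str, np.ndarray]

    def to_tsv(self) -> str:
        names = sorted(self.per_promoter)
        lines = ["\t".join(["time_h"] + names + ["total"])]
        for i, t in enumerate(self.time):
            row = [f"{t:.6g}"]
            row += [f"{self.per_promoter[n][i]:.6g}" for n in names]
            row.append(f"{self.total[i]:.6g}")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def trajectory_power(trajectory: Trajectory, netlist: CircuitNetlist,
                     assignment: Assignment,
                     library: GateLibrary) -> PowerSeries:
    """Evaluate the promoter-flux sum at every trajectory time point."""
    labels = [f"{d}@{c}" for d, c, _ in promoter_inventory(netlist)]
    per = {lab: np.empty_like(trajectory.time) for lab in labels}
    total = np.empty_like(trajectory.time)
    for i, t in enumerate(trajectory.time):
        bits = trajectory.schedule.bits_at(float(t))
        outputs = {name: arr[i]
                   for name, arr in trajectory.node_outputs.items()}
        _, occ, _ = node_fluxes(netlist, assignment, library, outputs,
                                bits, trajectory.model)
        entries = _entries_from(netlist, outputs, occ, trajectory.model)
        tot = 0.0
        for lab, flux in entries:
            per[lab][i] = flux
            tot += flux
        total[i] = tot
    return PowerSeries(time=trajectory.time, total=total, per_promoter=per)
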