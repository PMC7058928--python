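"""Circuit dynamics under piecewise-constant inducer schedules.

Gates relax toward the steady state dictated by their instantaneous input
with one of two first-order timescales:

    dy/dt = tau_on  * (y_ss - y)   if y < y_ss   (induction: transcription/
                                                  translation limited)
    dy/dt = tau_off * (y_ss - y)   otherwise     (relaxation: repressor
                                                  decay limited)

where ``y_ss`` is the gate's steady-state response to the tandem-composed
flux of its upstream promoters, evaluated with the interference correction
and the *current* upstream outputs.  Sensors relax with a single timescale
toward their OFF/ON level, and the reporter integrates the output promoter
flux against first-order degradation.  Between schedule segments the state
is continuous; only the sensor targets switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import FormatError, NumericalError, ScheduleError
from .gate_library import GateLibrary
from .steady_state import (INTERFERENCE, INPUT, NOR2, NOT, Assignment,
                           CircuitNetlist, compose_tandem, evaluate_state,
                           hill_response, roadblock_factor,
                           sensor_occupancy)

__all__ = ["InducerSchedule", "Trajectory", "relax", "simulate",
           "node_fluxes"]


# --------------------------------------------------------------------------
# Schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InducerSchedule:
    """Contiguous (start, end, sensor-state bits) segments starting at 0 h.

    Bits follow the netlist input order: ``bits[i]`` drives input i+1.
    """

    segments: tuple[tuple[float, float, tuple[int, ...]], ...]

    def __post_init__(self):
        if not self.segments:
            raise ScheduleError("schedule has no segments")
        if self.segments[0][0] != 0:
            raise ScheduleError("schedule must start at time 0")
        n = len(self.segments[0][2])
        prev_end = 0.0
        for start, end, bits in self.segments:
            if len(bits) != n:
                raise ScheduleError("inconsistent bit-vector lengths")
            if not end > start:
                raise ScheduleError(
                    f"segment [{start}, {end}] has non-positive duration")
            if not math.isclose(start, prev_end, abs_tol=1e-12):
                raise ScheduleError(
                    f"segment starting at {start} h leaves a gap or overlap "
                    f"after {prev_end} h")
            prev_end = end
        object.__setattr__(self, "_n_inputs", n)

    @property
    def n_inputs(self) -> int:
        return self._n_inputs

    @property
    def total_time(self) -> float:
        return self.segments[-1][1]

    def bits_at(self, t: float) -> tuple[int, ...]:
        for start, end, bits in self.segments:
            if start <= t < end:
                return bits
        if math.isclose(t, self.total_time, abs_tol=1e-9):
            return self.segments[-1][2]
        raise ScheduleError(f"time {t} h outside the schedule")

    @classmethod
    def from_states(cls, states: Sequence[Sequence[int]],
                    segment_hours: float) -> "InducerSchedule":
        segs = []
        for i, bits in enumerate(states):
            segs.append((i * segment_hours, (i + 1) * segment_hours,
                         tuple(int(b) for b in bits)))
        return cls(tuple(segs))

    def to_tsv(self) -> str:
        lines = []
        for start, end, bits in self.segments:
            vec = "".join(str(b) for b in reversed(bits))
            lines.append(f"{start:g}\t{end:g}\t{vec}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "InducerSchedule":
        segs = []
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"line {lineno}: expected 'start<TAB>end<TAB>bits'")
            try:
                start, end = float(parts[0]), float(parts[1])
                bits = tuple(int(c) for c in reversed(parts[2].strip()))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            segs.append((start, end, bits))
        return cls(tuple(segs))


# --------------------------------------------------------------------------
# Closed form for a single relaxation
# --------------------------------------------------------------------------

def relax(y0: float, y_ss: float, tau: float, t) -> float:
    """Exponential relaxation ``y_ss + (y0 - y_ss) * exp(-tau * t)``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = y_ss + (y0 - y_ss) * np.exp(-tau * t)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Flux bookkeeping shared with the power module
# --------------------------------------------------------------------------

def node_fluxes(netlist: CircuitNetlist, assignment: Assignment,
                library: GateLibrary, outputs: Mapping[str, float],
                bits: Sequence[int], model: str = INTERFERENCE):
    """Per-node (total_input, occupancy) plus the circuit output flux, for
    arbitrary instantaneous node outputs (not necessarily steady states)."""
    inputs = netlist.inputs
    bit_of = {nd.name: int(b) for nd, b in zip(inputs, bits)}
    x: dict[str, float] = {}
    occ: dict[str, float] = {}
    out_flux = 0.0
    for name in netlist.topological_order():
        nd = netlist.node(name)
        if nd.kind == INPUT:
            sensor = library.sensor(assignment.sensor_for(nd))
            x[name] = 0.0
            occ[name] = sensor_occupancy(sensor, bool(bit_of[name]))
            continue
        if len(nd.parents) == 1:
            xin = outputs[nd.parents[0]]
        else:
            up, down = nd.parents
            factor = occ[down] if model == INTERFERENCE else 1.0
            xin = compose_tandem(outputs[up], factor, outputs[down])
        x[name] = xin
        if nd.kind in (NOT, NOR2):
            gate = library.gate(assignment.gate_for(nd))
            occ[name] = roadblock_factor(gate, xin)
        else:
            occ[name] = 1.0
            out_flux = xin
    return x, occ, out_flux


# --------------------------------------------------------------------------
# Trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    time: np.ndarray                      # hours
    node_outputs: Mapping[str, np.ndarray]  # per node output flux (RPU)
    node_targets: Mapping[str, np.ndarray]  # instantaneous y_ss per node
    output_flux: np.ndarray               # composed flux at the reporter
    reporter: np.ndarray                  # reporter level (RPU-equivalent)
    schedule: InducerSchedule
    model: str

    def to_tsv(self) -> str:
        names = sorted(self.node_outputs)
        header = ["time_h"] + names + ["output_rpu", "reporter"]
        lines = ["\t".join(header)]
        for i, t in enumerate(self.time):
            row = [f"{t:.6g}"]
            row += [f"{self.node_outputs[n][i]:.6g}" for n in names]
            row += [f"{self.output_flux[i]:.6g}", f"{self.reporter[i]:.6g}"]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def simulate(netlist: CircuitNetlist, assignment: Assignment,
             library: GateLibrary, schedule: InducerSchedule,
             solver_options: dict | None = None,
             y0: Mapping[str, float] | None = None) -> Trajectory:
    """Integrate the circuit ODEs over an inducer schedule.

    The initial condition is the steady state of the first segment unless
    ``y0`` supplies per-node outputs (key "reporter" sets the reporter).
    """
    opts = {"rtol": 1e-8, "atol": 1e-10, "dt": 0.1, "method": "LSODA",
            "model": INTERFERENCE}
    opts.update(solver_options or {})
    model = opts["model"]

    if schedule.n_inputs != netlist.n_inputs:
        raise ScheduleError(
            f"schedule drives {schedule.n_inputs} inputs; netlist has "
            f"{netlist.n_inputs}")

    order = netlist.topological_order()
    sensor_nodes = [nd.name for nd in netlist.inputs]
    gate_nodes = [name for name in order
                  if netlist.node(name).kind in (NOT, NOR2)]
    dyn_nodes = sensor_nodes + gate_nodes
    idx = {name: i for i, name in enumerate(dyn_nodes)}
    n_dyn = len(dyn_nodes)

    sensors = {name: library.sensor(
        assignment.sensor_for(netlist.node(name))) for name in sensor_nodes}
    gates = {name: library.gate(assignment.gate_for(netlist.node(name)))
             for name in gate_nodes}
    reporter = library.reporter

    def targets_and_flux(outputs: Mapping[str, float],
                         bits: Sequence[int]) -> tuple[dict, float]:
        x, _, out_flux = node_fluxes(netlist, assignment, library, outputs,
                                     bits, model)
        yss = {}
        for name in sensor_nodes:
            s = sensors[name]
            bit = bits[sensor_nodes.index(name)]
            yss[name] = s.on_rpu if bit else s.off_rpu
        for name in gate_nodes:
            yss[name] = hill_response(gates[name], x[name])
        return yss, out_flux

    def rhs(t, v, bits):
        outputs = {name: v[idx[name]] for name in dyn_nodes}
        yss, out_flux = targets_and_flux(outputs, bits)
        dv = np.empty(n_dyn + 1)
        for name in sensor_nodes:
            dv[idx[name]] = sensors[name].tau_induction * \
                (yss[name] - v[idx[name]])
        for name in gate_nodes:
            g = gates[name]
            y = v[idx[name]]
            tau = g.tau_on if y < yss[name] else g.tau_off
            dv[idx[name]] = tau * (yss[name] - y)
        dv[n_dyn] = reporter.degradation_rate * \
            (reporter.production_scale * out_flux - v[n_dyn])
        return dv

    # initial condition
    first_bits = schedule.segments[0][2]
    if y0 is None:
        ss = evaluate_state(netlist, assignment, library, first_bits, model)
        v = np.empty(n_dyn + 1)
        for name in dyn_nodes:
            v[idx[name]] = ss.states[name].output_flux
        v[n_dyn] = reporter.production_scale * ss.output_flux
    else:
        v = np.empty(n_dyn + 1)
        for name in dyn_nodes:
            v[idx[name]] = y0[name]
        v[n_dyn] = y0.get("reporter", 0.0)

    times: list[np.ndarray] = []
    series: list[np.ndarray] = []
    for start, end, bits in schedule.segments:
        n_pts = max(int(round((end - start) / opts["dt"])), 2) + 1
        t_eval = np.linspace(start, end, n_pts)
        sol = solve_ivp(rhs, (start, end), v, t_eval=t_eval,
                        args=(bits,), method=opts["method"],
                        rtol=opts["rtol"], atol=opts["atol"])
        if not sol.success:
            raise NumericalError(
                f"ODE solver failed on segment [{start}, {end}] h: "
                f"{sol.message}")
        v = sol.y[:, -1]
        if times:  # drop the duplicated boundary point
            times.append(sol.t[1:])
            series.append(sol.y[:, 1:])
        else:
            times.append(sol.t)
            series.append(sol.y)
    t_all = np.concatenate(times)
    y_all = np.concatenate(series, axis=1)

    node_outputs = {name: y_all[idx[name]] for name in dyn_nodes}
    rep = y_all[n_dyn]

    out_flux = np.empty_like(t_all)
    targets = {name: np.empty_like(t_all) for name in dyn_nodes}
    for i, t in enumerate(t_all):
        bits = schedule.bits_at(float(t))
        outputs = {name: node_outputs[name][i] for name in dyn_nodes}
        yss, flux = targets_and_flux(outputs, bits)
        out_flux[i] = flux
        for name in dyn_nodes:
            targets[name][i] = yss[name]

    return Trajectory(time=t_all, node_outputs=node_outputs,
                      node_targets=targets, output_flux=out_flux,
                      reporter=rep, schedule=schedule, model=model)
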