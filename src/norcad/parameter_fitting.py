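"""Parameter estimation and synthetic-data generation.

Three fitters mirror the characterization workflow for a gate library:

* ``fit_hill`` — Hill response parameters (y_min, y_max, K, n) from a
  dose-response sweep.  Residuals are taken on log outputs because RPU
  dose-responses span about three orders of magnitude and errors are
  ratio-like.
* ``fit_interference`` — the interference parameters (alpha, beta) of a
  gate's output promoter from the four-point tandem "quadrant" experiment:
  an inducible promoter upstream, the gate's output promoter downstream,
  each toggled low/high.  Both parameters are capped at 1 during fitting.
* ``fit_timescales`` — the switching timescale (tau_on or tau_off) from a
  normalized reporter time course, with the sensor induction and reporter
  turnover chained into the forward model.

The companion generators produce datasets from the same forward models
with multiplicative lognormal noise (the conventional error model for
flow-cytometry medians), reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .errors import DataError
from .gate_library import GateRecord, ReporterRecord, SensorRecord
from .steady_state import hill_response, roadblock_factor

__all__ = [
    "DoseResponsePoint", "QuadrantData", "FitResult", "SyntheticDataset",
    "fit_hill", "fit_interference", "fit_timescales",
    "generate_sweep", "generate_quadrants", "generate_timecourse",
]

ON_TO_OFF, OFF_TO_ON = "on_to_off", "off_to_on"


# --------------------------------------------------------------------------
# Data carriers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponsePoint:
    x: float          # input flux, RPU
    y: float          # observed output flux, RPU
    replicate: int = 0


@dataclass(frozen=True)
class QuadrantData:
    """Four tandem-output observations keyed by (upstream_on,
    downstream_on) booleans."""

    observations: Mapping[tuple[bool, bool], float]

    def __post_init__(self):
        keys = {(False, False), (False, True), (True, False), (True, True)}
        if set(self.observations) != keys:
            missing = sorted(keys - set(self.observations))
            raise DataError(f"quadrant data must contain exactly the four "
                            f"inducer combinations; missing {missing}")


@dataclass(frozen=True)
class FitResult:
    estimates: dict[str, float]
    stderr: dict[str, float] | None
    residual_norm: float
    converged: bool
    constraint_active: dict[str, bool] = field(default_factory=dict)
    n_obs: int = 0


@dataclass(frozen=True)
class SyntheticDataset:
    kind: str
    observations: pd.DataFrame
    true_params: dict[str, float]
    noise_cv: float
    seed: int

    def to_tsv(self) -> str:
        return self.observations.to_csv(sep="\t", index=False,
                                        float_format="%.10g")


def _lognormal_factors(rng: np.random.Generator, cv: float,
                       size: int) -> np.ndarray:
    """Median-preserving multiplicative noise with the given CV."""
    if cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(size))


# --------------------------------------------------------------------------
# Hill response fitting
# --------------------------------------------------------------------------

def _as_xy(points) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for p in points:
        if isinstance(p, DoseResponsePoint):
            xs.append(p.x)
            ys.append(p.y)
        else:
            x, y = p[0], p[1]
            xs.append(x)
            ys.append(y)
    return np.asarray(xs, float), np.asarray(ys, float)


def fit_hill(points: Sequence, bounds: dict | None = None,
             seed: int = 0, n_starts: int = 10) -> FitResult:
    """Bounded nonlinear least squares for the declining Hill response,
    with log-output residuals and seeded multi-starts (the Hill exponent
    surface is multimodal)."""
    x, y = _as_xy(points)
    if len(x) < 5:
        raise DataError(f"fit_hill needs at least 5 points (got {len(x)})")
    if np.any(x < 0) or np.any(y <= 0):
        raise DataError("dose-response points need x >= 0 and y > 0")
    if x.max() <= x.min():
        raise DataError("dose-response points must span a range of inputs")

    b = {"y_min": (1e-8, np.inf), "dy": (1e-9, np.inf),
         "K": (1e-8, np.inf), "n": (0.5, 8.0)}
    b.update(bounds or {})
    lo = np.array([b["y_min"][0], b["dy"][0], b["K"][0], b["n"][0]])
    hi = np.array([b["y_min"][1], b["dy"][1], b["K"][1], b["n"][1]])

    identifiable = y.max() / y.min() > 1.2

    def residuals(theta):
        ymin, dy, K, n = theta
        kn = K ** n
        model = ymin + dy * kn / (kn + np.power(x, n))
        return np.log(model) - np.log(y)

    rng = np.random.default_rng(seed)
    xpos = x[x > 0]
    k0 = float(np.exp(np.mean(np.log(xpos)))) if len(xpos) else 0.1
    base = np.array([max(y.min(), 1e-6), max(y.max() - y.min(), 1e-6),
                     k0, 2.0])
    best = None
    for trial in range(max(n_starts, 1)):
        theta0 = base.copy()
        if trial > 0:
            theta0[:3] *= np.exp(0.7 * rng.standard_normal(3))
            theta0[3] = rng.uniform(0.5, 8.0)
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = least_squares(residuals, theta0, bounds=(lo, hi),
                                method="trf")
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return FitResult(estimates={}, stderr=None,
                         residual_norm=math.inf, converged=False,
                         n_obs=len(x))

    ymin, dy, K, n = best.x
    est = {"y_min": ymin, "y_max": ymin + dy, "K": K, "n": n}
    stderr = _stderr(best, ("y_min", "dy", "K", "n"))
    active = {"n": bool(n <= lo[3] + 1e-9 or n >= hi[3] - 1e-9)}
    return FitResult(estimates=est, stderr=stderr,
                     residual_norm=float(np.linalg.norm(best.fun)),
                     converged=bool(best.success and identifiable),
                     constraint_active=active, n_obs=len(x))


def _stderr(res, names) -> dict[str, float] | None:
    try:
        m, p = res.jac.shape
        if m <= p:
            return None
        s2 = 2 * res.cost / (m - p)
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
        return {nm: float(math.sqrt(max(cov[i, i], 0)))
                for i, nm in enumerate(names)}
    except np.linalg.LinAlgError:
        return None


# --------------------------------------------------------------------------
# Interference (alpha, beta) fitting
# --------------------------------------------------------------------------

def _quadrant_model(alpha: float, beta: float, gate2: GateRecord,
                    y1_levels: tuple[float, float],
                    x2_levels: tuple[float, float]) -> dict:
    g2 = replace(gate2, alpha=alpha, beta=beta)
    out = {}
    for up_on in (False, True):
        for down_on in (False, True):
            y1 = y1_levels[1] if up_on else y1_levels[0]
            x2 = x2_levels[1] if down_on else x2_levels[0]
            out[(up_on, down_on)] = (roadblock_factor(g2, x2) * y1
                                     + hill_response(gate2, x2))
    return out


def fit_interference(quadrants: QuadrantData, gate1: GateRecord | None,
                     gate2: GateRecord,
                     input_levels: Mapping[str, tuple[float, float]]
                     ) -> FitResult:
    """Least-squares fit of (alpha, beta) for ``gate2``'s output promoter
    from the four-point tandem experiment.

    ``input_levels["upstream"]`` gives the (low, high) input to the
    upstream stage: raw promoter flux when ``gate1`` is None (sensor
    upstream), otherwise the input flux into ``gate1`` whose Hill response
    then supplies the upstream flux.  ``input_levels["downstream"]`` gives
    the (low, high) input flux into ``gate2``.  Both parameters are bounded
    above by 1, matching the fitting convention for these factors.
    """
    up = tuple(input_levels["upstream"])
    down = tuple(input_levels["downstream"])
    if gate1 is not None:
        y1_levels = (hill_response(gate1, up[0]), hill_response(gate1, up[1]))
    else:
        y1_levels = up

    obs = quadrants.observations
    keys = [(False, False), (False, True), (True, False), (True, True)]
    target = np.array([obs[k] for k in keys])

    def residuals(theta):
        model = _quadrant_model(theta[0], theta[1], gate2, y1_levels, down)
        return np.array([model[k] for k in keys]) - target

    res = least_squares(residuals, x0=np.array([0.5, 0.5]),
                        bounds=(np.array([1e-9, 1e-9]),
                                np.array([1.0, 1.0])),
                        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    alpha, beta = res.x
    active = {"alpha": bool(alpha >= 1 - 1e-6),
              "beta": bool(beta >= 1 - 1e-6)}
    return FitResult(estimates={"alpha": float(alpha), "beta": float(beta)},
                     stderr=_stderr(res, ("alpha", "beta")),
                     residual_norm=float(np.linalg.norm(res.fun)),
                     converged=bool(res.success),
                     constraint_active=active, n_obs=4)


# --------------------------------------------------------------------------
# Switching-timescale fitting
# --------------------------------------------------------------------------

def _timecourse_model(tau: float, gate: GateRecord, direction: str,
                      sensor: SensorRecord, reporter: ReporterRecord,
                      t_grid: np.ndarray) -> np.ndarray:
    """Reporter trace for a single isolated gate switched at t = 0.

    The fitted tau drives the branch matching the experiment's direction;
    the opposite branch keeps the gate's recorded timescale.
    """
    if direction == ON_TO_OFF:
        s0, s_target = sensor.off_rpu, sensor.on_rpu
        tau_on, tau_off = gate.tau_on, tau
    elif direction == OFF_TO_ON:
        s0, s_target = sensor.on_rpu, sensor.off_rpu
        tau_on, tau_off = tau, gate.tau_off
    else:
        raise ValueError(f"direction must be {ON_TO_OFF!r} or {OFF_TO_ON!r}")
    y0 = hill_response(gate, s0)
    Y0 = reporter.production_scale * y0

    def rhs(t, v):
        s, y, Y = v
        ds = sensor.tau_induction * (s_target - s)
        yss = hill_response(gate, s)
        tt = tau_on if y < yss else tau_off
        dy = tt * (yss - y)
        dY = reporter.degradation_rate * \
            (reporter.production_scale * y - Y)
        return (ds, dy, dY)

    sol = solve_ivp(rhs, (float(t_grid[0]), float(t_grid[-1])),
                    (s0, y0, Y0), t_eval=t_grid, method="LSODA",
                    rtol=1e-9, atol=1e-12)
    return sol.y[2]


def fit_timescales(timecourse: Sequence, direction: str,
                   context: Mapping[str, object]) -> FitResult:
    """Fit one switching timescale to a normalized reporter time course.

    ``context`` supplies "gate" (GateRecord with known steady-state
    endpoints), "sensor" (SensorRecord) and "reporter" (ReporterRecord).
    Observations are normalized by the value at the earliest time, so the
    fit is invariant to overall scaling of the trace.
    """
    t, y = _as_xy(timecourse)
    if len(t) < 4:
        raise DataError(f"fit_timescales needs at least 4 time points "
                        f"(got {len(t)})")
    order = np.argsort(t)
    t, y = t[order], y[order]
    ynorm = y / y[0]
    if (y.max() - y.min()) / max(y.mean(), 1e-12) < 1e-3:
        return FitResult(estimates={}, stderr=None, residual_norm=0.0,
                         converged=False, n_obs=len(t))

    gate: GateRecord = context["gate"]
    sensor: SensorRecord = context["sensor"]
    reporter: ReporterRecord = context.get("reporter", ReporterRecord())

    def residuals(theta):
        model = _timecourse_model(float(theta[0]), gate, direction,
                                  sensor, reporter, t)
        return model / model[0] - ynorm

    # coarse log-spaced grid then a bounded local refinement
    grid = np.geomspace(0.05, 20.0, 8)
    costs = [float(np.sum(residuals([g]) ** 2)) for g in grid]
    tau0 = float(grid[int(np.argmin(costs))])
    res = least_squares(residuals, x0=[tau0], bounds=([1e-3], [50.0]),
                        method="trf", xtol=1e-12, ftol=1e-12)
    tau = float(res.x[0])
    name = "tau_off" if direction == ON_TO_OFF else "tau_on"
    return FitResult(estimates={name: tau}, stderr=_stderr(res, (name,)),
                     residual_norm=float(np.linalg.norm(res.fun)),
                     converged=bool(res.success),
                     constraint_active={name: bool(tau <= 1.1e-3
                                                   or tau >= 49.9)},
                     n_obs=len(t))


# --------------------------------------------------------------------------
# Synthetic data generators
# --------------------------------------------------------------------------

_DEFAULT_SWEEP = np.geomspace(0.005, 5.0, 18)


def generate_sweep(gate: GateRecord, n_points: int = 18,
                   noise_cv: float = 0.0, seed: int = 0,
                   x_grid: np.ndarray | None = None) -> SyntheticDataset:
    """Dose-response sweep from the gate's Hill response (default 18 input
    levels spanning the dynamic range) with lognormal noise."""
    if x_grid is None:
        x_grid = (np.geomspace(0.005, 5.0, n_points) if n_points != 18
                  else _DEFAULT_SWEEP)
    x = np.asarray(x_grid, float)
    rng = np.random.default_rng(seed)
    y = np.array([hill_response(gate, xi) for xi in x])
    y = y * _lognormal_factors(rng, noise_cv, len(x))
    df = pd.DataFrame({"x_rpu": x, "y_rpu": y,
                       "replicate": np.zeros(len(x), int)})
    truth = {"y_min": gate.y_min, "y_max": gate.y_max, "K": gate.K,
             "n": gate.n}
    return SyntheticDataset(kind="dose_response", observations=df,
                            true_params=truth, noise_cv=noise_cv, seed=seed)


def generate_quadrants(gate1: GateRecord | None, gate2: GateRecord,
                       alpha: float, beta: float,
                       input_levels: Mapping[str, tuple[float, float]],
                       noise_cv: float = 0.0,
                       seed: int = 0) -> SyntheticDataset:
    """Four-point tandem dataset from the interference composition model."""
    up = tuple(input_levels["upstream"])
    down = tuple(input_levels["downstream"])
    if gate1 is not None:
        y1_levels = (hill_response(gate1, up[0]), hill_response(gate1, up[1]))
    else:
        y1_levels = up
    model = _quadrant_model(alpha, beta, gate2, y1_levels, down)
    keys = [(False, False), (False, True), (True, False), (True, True)]
    rng = np.random.default_rng(seed)
    noise = _lognormal_factors(rng, noise_cv, 4)
    rows = [{"upstream_on": int(k[0]), "downstream_on": int(k[1]),
             "y_rpu": model[k] * noise[i]} for i, k in enumerate(keys)]
    df = pd.DataFrame(rows)
    return SyntheticDataset(kind="quadrants", observations=df,
                            true_params={"alpha": alpha, "beta": beta},
                            noise_cv=noise_cv, seed=seed)


def generate_timecourse(gate: GateRecord, direction: str,
                        grid: np.ndarray | None = None,
                        noise_cv: float = 0.0, seed: int = 0,
                        sensor: SensorRecord | None = None,
                        reporter: ReporterRecord | None = None
                        ) -> SyntheticDataset:
    """Reporter time course for a single gate switched at t = 0, using the
    gate's recorded timescales as ground truth."""
    if grid is None:
        grid = np.linspace(0.0, 8.0, 17)
    grid = np.asarray(grid, float)
    if sensor is None:
        sensor = SensorRecord("P_in", "P_in", 0.02, 2.0, tau_induction=1.0)
    if reporter is None:
        reporter = ReporterRecord()
    tau = gate.tau_off if direction == ON_TO_OFF else gate.tau_on
    trace = _timecourse_model(tau, gate, direction, sensor, reporter, grid)
    rng = np.random.default_rng(seed)
    trace = trace * _lognormal_factors(rng, noise_cv, len(grid))
    df = pd.DataFrame({"time_h": grid, "y": trace,
                       "replicate": np.zeros(len(grid), int)})
    truth = {"tau_off" if direction == ON_TO_OFF else "tau_on": tau}
    return SyntheticDataset(kind=f"timecourse_{direction}", observations=df,
                            true_params=truth, noise_cv=noise_cv, seed=seed)
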