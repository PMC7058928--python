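"""Gate/sensor library data model and I/O.

A *library* bundles everything the designer knows about a strain's gate
technology: the repressor-based NOT/NOR gates with their Hill response
functions, tandem-promoter interference parameters (non-specific factor
``alpha`` and roadblock factor ``beta``), and two-timescale switching
kinetics; the inducible sensors with their OFF/ON promoter activities in
relative promoter units (RPU); the reporter kinetics; and the layout rules
that constrain how gates may be ordered on the final linear DNA construct.

The on-disk dialect is a UCF-style JSON document: named-parameter blocks
per gate, with the interference block written as a list of
``{"name": ..., "value": ...}`` pairs.  When the interference block is
absent the gate falls back to ``alpha = beta = 1``, which reduces every
downstream prediction to the plain additive tandem-promoter model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

from .errors import FormatError, ValidationError

__all__ = [
    "GateRecord",
    "SensorRecord",
    "ReporterRecord",
    "LayoutRules",
    "GateLibrary",
    "load_library",
    "loads_library",
    "save_library",
    "dumps_library",
    "builtin_library",
    "validate_library",
]


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GateRecord:
    """One repressor gate.

    Parameters
    ----------
    y_min, y_max
        Output promoter activity (RPU) at full repression / full induction.
    K
        Input flux (RPU) at the half-maximal response.
    n
        Hill coefficient (cooperativity), dimensionless.
    alpha
        Non-specific interference factor in (0, 1]: suppression of an
        upstream tandem promoter that does not depend on repressor binding.
    beta
        Roadblock factor in (0, 1]: residual upstream read-through when the
        repressor is bound at this gate's output promoter.  Small beta means
        a tightly bound repressor that elongating RNAP cannot dislodge.
    tau_on, tau_off
        Switching timescales (1/h) toward a higher / lower steady state.
    """

    name: str
    repressor_family: str
    y_min: float
    y_max: float
    K: float
    n: float
    alpha: float = 1.0
    beta: float = 1.0
    tau_on: float = 1.0
    tau_off: float = 1.0

    def issues(self) -> list[str]:
        out = []
        if not (0 < self.y_min < self.y_max):
            out.append(f"gate {self.name}: requires 0 < y_min < y_max "
                       f"(got y_min={self.y_min}, y_max={self.y_max})")
        if not self.K > 0:
            out.append(f"gate {self.name}: K must be > 0 (got {self.K})")
        if not self.n > 0:
            out.append(f"gate {self.name}: n must be > 0 (got {self.n})")
        for pname in ("alpha", "beta"):
            v = getattr(self, pname)
            if not (0 < v <= 1):
                out.append(f"gate {self.name}: {pname} must lie in (0, 1] "
                           f"(got {v})")
        for pname in ("tau_on", "tau_off"):
            v = getattr(self, pname)
            if not v > 0:
                out.append(f"gate {self.name}: {pname} must be > 0 (got {v})")
        return out


@dataclass(frozen=True)
class SensorRecord:
    """An inducible input system, identified by its output promoter."""

    name: str
    promoter_name: str
    off_rpu: float
    on_rpu: float
    alpha: float = 1.0
    beta: float = 1.0
    tau_induction: float = 1.0
    mode: str = "repressor-based"  # or "activator-based"

    def issues(self) -> list[str]:
        out = []
        if not (0 < self.off_rpu < self.on_rpu):
            out.append(f"sensor {self.name}: requires 0 < off_rpu < on_rpu "
                       f"(got {self.off_rpu}, {self.on_rpu})")
        for pname in ("alpha", "beta"):
            v = getattr(self, pname)
            if not (0 < v <= 1):
                out.append(f"sensor {self.name}: {pname} must lie in (0, 1] "
                           f"(got {v})")
        if not self.tau_induction > 0:
            out.append(f"sensor {self.name}: tau_induction must be > 0")
        if self.mode not in ("repressor-based", "activator-based"):
            out.append(f"sensor {self.name}: unknown mode {self.mode!r}")
        return out


@dataclass(frozen=True)
class ReporterRecord:
    """Reporter (YFP) kinetics.

    ``production_scale`` is chosen so that a constant output flux F (RPU)
    drives the reporter to a steady level of ``production_scale * F``; the
    default of 1 keeps reporter traces directly comparable to RPU.
    """

    degradation_rate: float = 0.5  # 1/h
    production_scale: float = 1.0

    def issues(self) -> list[str]:
        out = []
        if not self.degradation_rate > 0:
            out.append("reporter: degradation_rate must be > 0")
        if not self.production_scale > 0:
            out.append("reporter: production_scale must be > 0")
        return out


@dataclass(frozen=True)
class LayoutRules:
    """Eugene-style constraints on the linear construct layout."""

    gate_order: tuple[str, ...]
    scar_order: tuple[str, ...]
    prohibited_pairs: frozenset[frozenset[str]] = frozenset()
    same_family_once: bool = True

    def issues(self) -> list[str]:
        out = []
        if len(set(self.gate_order)) != len(self.gate_order):
            out.append("layout: gate_order contains duplicates")
        if self.scar_order and (self.scar_order[0] != "A"
                                or self.scar_order[-1] != "C"):
            out.append("layout: scar_order must begin with 'A' and end "
                       "with 'C'")
        for pair in self.prohibited_pairs:
            for fam in pair:
                if fam not in self.gate_order:
                    out.append(f"layout: prohibited-pair member {fam!r} "
                               "missing from gate_order")
        return out


@dataclass
class GateLibrary:
    gates: tuple[GateRecord, ...]
    sensors: tuple[SensorRecord, ...]
    reporter: ReporterRecord = field(default_factory=ReporterRecord)
    layout: LayoutRules = field(
        default_factory=lambda: LayoutRules(gate_order=(), scar_order=()))
    metadata: dict = field(default_factory=dict)

    def gate(self, name: str) -> GateRecord:
        for g in self.gates:
            if g.name == name:
                return g
        raise KeyError(f"no gate named {name!r} in library")

    def sensor(self, name: str) -> SensorRecord:
        for s in self.sensors:
            if s.name == name:
                return s
        raise KeyError(f"no sensor named {name!r} in library")

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.gates:
            seen.setdefault(g.repressor_family, None)
        return list(seen)

    def gates_by_family(self) -> dict[str, list[GateRecord]]:
        fam: dict[str, list[GateRecord]] = {}
        for g in self.gates:
            fam.setdefault(g.repressor_family, []).append(g)
        return fam


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def validate_library(lib: GateLibrary) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    issues: list[str] = []
    if not lib.gates:
        issues.append("library: gate list is empty")
    names = [g.name for g in lib.gates]
    for name in sorted({n for n in names if names.count(n) > 1}):
        issues.append(f"library: duplicate gate name {name!r}")
    snames = [s.name for s in lib.sensors]
    for name in sorted({n for n in snames if snames.count(n) > 1}):
        issues.append(f"library: duplicate sensor name {name!r}")
    for g in lib.gates:
        issues.extend(g.issues())
    for s in lib.sensors:
        issues.extend(s.issues())
    issues.extend(lib.reporter.issues())
    issues.extend(lib.layout.issues())
    return issues


# --------------------------------------------------------------------------
# JSON dialect
# --------------------------------------------------------------------------

_GATE_KEYS = {"name", "repressor_family", "response_function", "interference",
              "kinetics"}
_SENSOR_KEYS = {"name", "promoter_name", "off_rpu", "on_rpu", "interference",
                "tau_induction", "mode"}
_TOP_KEYS = {"collection", "gates", "sensors", "reporter", "layout_rules",
             "metadata"}


def _interference_pairs(block: Any, where: str) -> dict[str, float]:
    """Decode the UCF-style ``[{"name": ..., "value": ...}]`` block."""
    out: dict[str, float] = {}
    if block is None:
        return out
    if not isinstance(block, list):
        raise FormatError(f"{where}: interference block must be a list of "
                          "name/value pairs")
    for item in block:
        try:
            out[item["name"]] = float(item["value"])
        except (TypeError, KeyError) as exc:
            raise FormatError(f"{where}: malformed interference entry "
                              f"{item!r}") from exc
    return out


def _decode_gate(obj: dict, unknown: dict) -> GateRecord:
    where = f"gate {obj.get('name', '?')!r}"
    try:
        rf = obj["response_function"]
        kin = obj.get("kinetics", {})
        inter = _interference_pairs(obj.get("interference"), where)
        rec = GateRecord(
            name=obj["name"],
            repressor_family=obj["repressor_family"],
            y_min=float(rf["y_min"]),
            y_max=float(rf["y_max"]),
            K=float(rf["K"]),
            n=float(rf["n"]),
            alpha=float(inter.get("alpha", 1.0)),
            beta=float(inter.get("beta", 1.0)),
            tau_on=float(kin.get("tau_on", 1.0)),
            tau_off=float(kin.get("tau_off", 1.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{where}: missing or malformed field: {exc}") \
            from exc
    extra = {k: obj[k] for k in obj if k not in _GATE_KEYS}
    if extra:
        unknown[f"gate:{rec.name}"] = extra
    return rec


def _decode_sensor(obj: dict, unknown: dict) -> SensorRecord:
    where = f"sensor {obj.get('name', '?')!r}"
    try:
        inter = _interference_pairs(obj.get("interference"), where)
        rec = SensorRecord(
            name=obj["name"],
            promoter_name=obj.get("promoter_name", obj["name"]),
            off_rpu=float(obj["off_rpu"]),
            on_rpu=float(obj["on_rpu"]),
            alpha=float(inter.get("alpha", 1.0)),
            beta=float(inter.get("beta", 1.0)),
            tau_induction=float(obj.get("tau_induction", 1.0)),
            mode=obj.get("mode", "repressor-based"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{where}: missing or malformed field: {exc}") \
            from exc
    extra = {k: obj[k] for k in obj if k not in _SENSOR_KEYS}
    if extra:
        unknown[f"sensor:{rec.name}"] = extra
    return rec


def loads_library(text: str) -> GateLibrary:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"library is not valid JSON: line {exc.lineno}, "
                          f"column {exc.colno}: {exc.msg}") from exc
    if not isinstance(doc, dict):
        raise FormatError("library document must be a JSON object")

    unknown: dict[str, Any] = {}
    gates = tuple(_decode_gate(g, unknown) for g in doc.get("gates", []))
    sensors = tuple(_decode_sensor(s, unknown)
                    for s in doc.get("sensors", []))

    rep = doc.get("reporter", {})
    reporter = ReporterRecord(
        degradation_rate=float(rep.get("degradation_rate", 0.5)),
        production_scale=float(rep.get("production_scale", 1.0)),
    )

    lay = doc.get("layout_rules", {})
    layout = LayoutRules(
        gate_order=tuple(lay.get("gate_order", [])),
        scar_order=tuple(lay.get("scar_order", [])),
        prohibited_pairs=frozenset(
            frozenset(p) for p in lay.get("prohibited_pairs", [])),
        same_family_once=bool(lay.get("same_family_once", True)),
    )

    metadata = dict(doc.get("metadata", {}))
    top_extra = {k: doc[k] for k in doc if k not in _TOP_KEYS}
    if top_extra:
        metadata["unknown_fields_top"] = top_extra
    if unknown:
        metadata["unknown_fields"] = unknown

    lib = GateLibrary(gates=gates, sensors=sensors, reporter=reporter,
                      layout=layout, metadata=metadata)
    issues = validate_library(lib)
    if issues:
        raise ValidationError("library failed validation:\n  "
                              + "\n  ".join(issues))
    return lib


def load_library(path) -> GateLibrary:
    """Load and validate a UCF-style JSON library file."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_library(fh.read())


def _encode_gate(g: GateRecord, unknown: dict) -> dict:
    obj = {
        "name": g.name,
        "repressor_family": g.repressor_family,
        "response_function": {"y_min": g.y_min, "y_max": g.y_max,
                              "K": g.K, "n": g.n},
        "interference": [{"name": "alpha", "value": g.alpha},
                         {"name": "beta", "value": g.beta}],
        "kinetics": {"tau_on": g.tau_on, "tau_off": g.tau_off},
    }
    obj.update(unknown.get(f"gate:{g.name}", {}))
    return obj


def _encode_sensor(s: SensorRecord, unknown: dict) -> dict:
    obj = {
        "name": s.name,
        "promoter_name": s.promoter_name,
        "off_rpu": s.off_rpu,
        "on_rpu": s.on_rpu,
        "interference": [{"name": "alpha", "value": s.alpha},
                         {"name": "beta", "value": s.beta}],
        "tau_induction": s.tau_induction,
        "mode": s.mode,
    }
    obj.update(unknown.get(f"sensor:{s.name}", {}))
    return obj


def dumps_library(lib: GateLibrary) -> str:
    metadata = dict(lib.metadata)
    unknown = metadata.pop("unknown_fields", {})
    top_extra = metadata.pop("unknown_fields_top", {})
    doc: dict[str, Any] = {"collection": "norcad-library"}
    doc["gates"] = [_encode_gate(g, unknown) for g in lib.gates]
    doc["sensors"] = [_encode_sensor(s, unknown) for s in lib.sensors]
    doc["reporter"] = {"degradation_rate": lib.reporter.degradation_rate,
                       "production_scale": lib.reporter.production_scale}
    doc["layout_rules"] = {
        "gate_order": list(lib.layout.gate_order),
        "scar_order": list(lib.layout.scar_order),
        "prohibited_pairs": sorted(sorted(p) for p in
                                   lib.layout.prohibited_pairs),
        "same_family_once": lib.layout.same_family_once,
    }
    doc["metadata"] = metadata
    doc.update(top_extra)
    return json.dumps(doc, indent=2) + "\n"


def save_library(lib: GateLibrary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_library(lib))


# --------------------------------------------------------------------------
# Packaged fixture
# --------------------------------------------------------------------------

def builtin_library() -> GateLibrary:
    """The packaged 18-gate / 4-sensor *E. coli* NOR-gate library.

    Gate parameters transcribe the published characterization of the
    low-copy p15a gate set (Hill response, interference factors, switching
    timescales).  Sensor OFF/ON activities are the published RPU levels for
    P_Tac, P_Tet, P_Lux2 and P_Cin.  Sensor interference parameters are not
    published; they default to alpha = beta = 1 (purely additive behavior)
    and are flagged as defaults in the file's metadata.
    """
    text = (resources.files("norcad") / "data" /
            "eco_nor_library.json").read_text(encoding="utf-8")
    return loads_library(text)
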