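"""Gate/sensor library data model and JSON I/O.

A *gate library* bundles everything needed to predict a transcriptional
NOR-gate circuit at steady state: the Hill repression response of each
NOT gate (measured in relative promoter units against a genome-integrated
reference, RPU_G), the OFF/ON output activities of each small-molecule
sensor, the engine constants that convert RPU_G into absolute RNA-polymerase
flux, and the growth-score cutoff used to reject burdensome designs.

The on-disk format is a minimal JSON document (see ``data/library.schema.json``
for a human-readable description).  It is deliberately *not* the full
user-constraint-file format consumed by circuit design automation tools,
which additionally carries cytometry histograms, part sequences and
placement rules; this library holds only the quantitative model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable


class LibraryError(ValueError):
    """Structural problem with a gate library (e.g. duplicate names)."""


class ValidationError(ValueError):
    """A field violates its invariant; the message names the field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class HillParams:
    """Parameters of a repression Hill function.

    y(x) = y_min + (y_max - y_min) / (1 + (x / K)^n)

    All promoter activities are in RPU_G.  ``K`` is the input activity at
    which the output falls halfway between ``y_max`` and ``y_min``; ``n``
    is the (dimensionless) cooperativity.
    """

    y_max: float
    y_min: float
    K: float
    n: float

    def __post_init__(self) -> None:
        _require(0 <= self.y_min, "y_min", "must be >= 0")
        _require(self.y_min < self.y_max, "y_max", "must exceed y_min")
        _require(self.K > 0, "K", "must be > 0")
        _require(self.n > 0, "n", "must be > 0")


@dataclass(frozen=True)
class GrowthLine:
    """Linear model of relative OD600 versus gate input activity.

    ``intercept`` is the relative growth at zero input; ``slope`` is the
    change per RPU_G of input.  A neutral gate is (1.0, 0.0).
    """

    intercept: float = 1.0
    slope: float = 0.0

    def __post_init__(self) -> None:
        _require(0 < self.intercept <= 1.5, "intercept", "must be in (0, 1.5]")

    def __call__(self, x: float) -> float:
        return self.intercept + self.slope * x


@dataclass(frozen=True)
class GateModel:
    """One repressor-based NOT gate."""

    name: str
    repressor: str
    response: HillParams
    growth: GrowthLine = GrowthLine()
    noise_cv: float = 0.3

    def __post_init__(self) -> None:
        _require(self.noise_cv >= 0, "noise_cv", "must be >= 0")


@dataclass(frozen=True)
class SensorModel:
    """A small-molecule sensor characterized by its OFF/ON output promoter
    activities (RPU_G).  ``dose_response`` optionally holds an activation
    Hill (K_ind in inducer concentration units, n_ind dimensionless)."""

    name: str
    inducer: str
    y_min: float
    y_max: float
    dose_response: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        _require(0 <= self.y_min, "y_min", "must be >= 0")
        _require(self.y_min < self.y_max, "y_max", "must exceed y_min")


@dataclass(frozen=True)
class ConversionConstants:
    """Constants tying RPU_G to absolute units.

    flux_per_rpu_per_dna : RNAP/s per RPU per DNA copy.
    landing_pad_copy_number : effective copy number of the genomic site
        carrying the reference promoter (origin-proximal sites replicate
        ahead of the terminus, so this exceeds 1).
    rpug_per_rpu : divisor converting genome-referenced RPU_G into
        plasmid-referenced RPU.
    """

    flux_per_rpu_per_dna: float = 0.019
    landing_pad_copy_number: float = 3.5
    rpug_per_rpu: float = 6.33

    def __post_init__(self) -> None:
        for f in ("flux_per_rpu_per_dna", "landing_pad_copy_number", "rpug_per_rpu"):
            _require(getattr(self, f) > 0, f, "must be > 0")


@dataclass(frozen=True)
class GateLibrary:
    gates: tuple[GateModel, ...]
    sensors: tuple[SensorModel, ...]
    constants: ConversionConstants = ConversionConstants()
    growth_cutoff: float = 0.75

    def __post_init__(self) -> None:
        _require(0 <= self.growth_cutoff <= 1, "growth_cutoff", "must be in [0, 1]")
        names = [g.name for g in self.gates]
        if len(set(names)) != len(names):
            raise LibraryError("duplicate gate name in library")
        reps = [g.repressor for g in self.gates]
        if len(set(reps)) != len(reps):
            raise LibraryError("duplicate repressor identifier in library")
        snames = [s.name for s in self.sensors]
        if len(set(snames)) != len(snames):
            raise LibraryError("duplicate sensor name in library")

    def gate(self, name: str) -> GateModel:
        for g in self.gates:
            if g.name == name:
                return g
        raise KeyError(name)

    def gate_by_repressor(self, repressor: str) -> GateModel:
        for g in self.gates:
            if g.repressor == repressor:
                return g
        raise KeyError(repressor)

    def sensor(self, name: str) -> SensorModel:
        for s in self.sensors:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def repressors(self) -> tuple[str, ...]:
        return tuple(g.repressor for g in self.gates)


# ---------------------------------------------------------------------------
# JSON serialization


def _num(value, field_name: str) -> float:
    """Accept IEEE doubles or decimal strings."""
    if isinstance(value, bool) or value is None:
        raise ValidationError(f"{field_name}: expected a number, got {value!r}")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{field_name}: not a number: {value!r}") from None


def _gate_from_dict(d: dict) -> GateModel:
    try:
        resp = d["response"]
        params = HillParams(
            y_max=_num(resp["y_max"], "response.y_max"),
            y_min=_num(resp["y_min"], "response.y_min"),
            K=_num(resp["K"], "response.K"),
            n=_num(resp["n"], "response.n"),
        )
        growth = d.get("growth", {})
        return GateModel(
            name=d["name"],
            repressor=d["repressor"],
            response=params,
            growth=GrowthLine(
                intercept=_num(growth.get("intercept", 1.0), "growth.intercept"),
                slope=_num(growth.get("slope", 0.0), "growth.slope"),
            ),
            noise_cv=_num(d.get("noise_cv", 0.3), "noise_cv"),
        )
    except KeyError as e:
        raise ValidationError(f"gate missing required field {e.args[0]!r}") from None


def _sensor_from_dict(d: dict) -> SensorModel:
    try:
        dr = d.get("dose_response")
        return SensorModel(
            name=d["name"],
            inducer=d.get("inducer", ""),
            y_min=_num(d["y_min"], "sensor.y_min"),
            y_max=_num(d["y_max"], "sensor.y_max"),
            dose_response=None
            if dr is None
            else (_num(dr["K_ind"], "dose_response.K_ind"), _num(dr["n_ind"], "dose_response.n_ind")),
        )
    except KeyError as e:
        raise ValidationError(f"sensor missing required field {e.args[0]!r}") from None


def library_from_dict(doc: dict) -> GateLibrary:
    if not isinstance(doc, dict):
        raise ValidationError("document: top level must be a JSON object")
    for key in ("gates", "sensors"):
        if key not in doc or not isinstance(doc[key], list):
            raise ValidationError(f"{key}: required list is missing or not a list")
    const = doc.get("constants", {})
    return GateLibrary(
        gates=tuple(_gate_from_dict(g) for g in doc["gates"]),
        sensors=tuple(_sensor_from_dict(s) for s in doc["sensors"]),
        constants=ConversionConstants(
            flux_per_rpu_per_dna=_num(const.get("flux_per_rpu_per_dna", 0.019), "constants.flux_per_rpu_per_dna"),
            landing_pad_copy_number=_num(const.get("landing_pad_copy_number", 3.5), "constants.landing_pad_copy_number"),
            rpug_per_rpu=_num(const.get("rpug_per_rpu", 6.33), "constants.rpug_per_rpu"),
        ),
        growth_cutoff=_num(doc.get("growth_cutoff", 0.75), "growth_cutoff"),
    )


def library_to_dict(lib: GateLibrary) -> dict:
    doc = {
        "gates": [
            {
                "name": g.name,
                "repressor": g.repressor,
                "response": asdict(g.response),
                "growth": asdict(g.growth),
                "noise_cv": g.noise_cv,
            }
            for g in lib.gates
        ],
        "sensors": [
            {
                "name": s.name,
                "inducer": s.inducer,
                "y_min": s.y_min,
                "y_max": s.y_max,
                **(
                    {"dose_response": {"K_ind": s.dose_response[0], "n_ind": s.dose_response[1]}}
                    if s.dose_response is not None
                    else {}
                ),
            }
            for s in lib.sensors
        ],
        "constants": asdict(lib.constants),
        "growth_cutoff": lib.growth_cutoff,
    }
    return doc


def load_library(path: str | Path) -> GateLibrary:
    """Load and validate a gate library from a JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return library_from_dict(doc)


def save_library(lib: GateLibrary, path: str | Path) -> None:
    """Write the library as UTF-8 JSON.  Python's shortest-repr float
    encoding makes load(save(L)) bit-exact for every numeric field."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(library_to_dict(lib), fh, indent=1)
        fh.write("\n")


def packaged_library() -> GateLibrary:
    """The library shipped with the package: six genome-characterized
    NOT gates and seven sensor output promoters (activities in RPU_G),
    with default conversion constants.

    Per-gate cytometry noise and growth coefficients are not part of the
    published parameter table, so the packaged gates carry the documented
    defaults (noise_cv = 0.3, neutral growth); users fit real values with
    :mod:`gencirc.quantitation`.
    """
    ref = resources.files("gencirc").joinpath("data/genome_gate_library.json")
    return library_from_dict(json.loads(ref.read_text(encoding="utf-8")))
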