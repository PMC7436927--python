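"""Synthetic-data generators with the statistical structure the analysis
assumes: lognormal cytometry populations, Hill-shaped dose-response curves
with replicate noise, and Poisson-sampled strand-specific coverage profiles
with step drops at planted terminators.

All generators are pure functions of (parameters, seed): identical calls
produce byte-identical output.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import TruthTable
from .insulation import TerminatorAnnotation
from .library import GateModel, HillParams, SensorModel
from .quantitation import CytometrySample, hill_response


@dataclass(frozen=True)
class SimSpec:
    """Shared simulation conditions.

    n_events mirrors typical cytometry acquisition (>30,000 events per
    sample); replicates mirrors the three-day experimental design; depth is
    the mean per-base read coverage of the coverage simulator.
    """

    seed: int = 42
    n_events: int = 30_000
    noise_cv: float = 0.3
    replicates: int = 3
    depth: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates <= 0:
            raise ValueError("replicates must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


def _sigma_log(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def gen_cytometry(
    median: float, spec: SimSpec, channel: str = "FITC-A", condition: str = ""
) -> CytometrySample:
    """Lognormal single-cell fluorescence population with the requested
    median and coefficient of variation (CV = 0 gives a point mass)."""
    if median <= 0:
        raise ValueError("median must be > 0")
    rng = np.random.default_rng(spec.seed)
    sigma = _sigma_log(spec.noise_cv)
    events = median * np.exp(sigma * rng.standard_normal(spec.n_events))
    return CytometrySample(events=events, channel=channel, condition=condition)


def gen_response_curve(
    gate: GateModel,
    sensor: SensorModel,
    spec: SimSpec,
    n_points: int = 12,
) -> tuple[pd.DataFrame, HillParams]:
    """Simulated gate dose-response measurement.

    Input activities are log-spaced across the driving sensor's dynamic
    range [y_min, y_max] at ``n_points`` (the characterization design uses
    12 inducer concentrations); each replicate output is the gate's Hill
    response times lognormal noise (median-unbiased).  Returns the tidy
    table (input_rpug, replicate, output_rpug) and the generating
    parameters as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.logspace(
        math.log10(sensor.y_min), math.log10(sensor.y_max), n_points
    )
    truth = gate.response
    y_true = hill_response(truth, x)
    sigma = _sigma_log(spec.noise_cv)
    rows = []
    for rep in range(1, spec.replicates + 1):
        noise = np.exp(sigma * rng.standard_normal(n_points))
        for xi, yi in zip(x, y_true * noise):
            rows.append({"input_rpug": xi, "replicate": rep, "output_rpug": yi})
    return pd.DataFrame(rows), truth


def gen_coverage(
    replicon_len: int,
    units: list[tuple[int, int, str, float]],
    terminators: list[tuple[TerminatorAnnotation, float]],
    spec: SimSpec,
) -> dict:
    """Simulate strand-specific raw read counts for planted transcription
    units and terminators.

    ``units`` are (start, end, strand, expression_level) in 1-based
    inclusive coordinates; same-strand units must not overlap.
    ``terminators`` are (annotation, true_readthrough) and must lie inside
    a same-strand unit.  Expected coverage is piecewise constant: within a
    unit it equals depth * expression, multiplied by the cumulative
    readthrough of every terminator the polymerase has already crossed;
    per-base counts are Poisson.  Returns
    {"sense": counts, "antisense": counts, "truth": {...}}.
    """
    expected = {
        "sense": np.zeros(replicon_len, dtype=float),
        "antisense": np.zeros(replicon_len, dtype=float),
    }
    strand_key = {"+": "sense", "-": "antisense"}
    # overlap check per strand
    for strand in ("+", "-"):
        spans = sorted((s, e) for s, e, st, _ in units if st == strand)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("overlapping same-strand units")

    for start, end, strand, level in units:
        if not (1 <= start <= end <= replicon_len):
            raise ValueError("unit outside replicon")
        arr = expected[strand_key[strand]]
        arr[start - 1 : end] = spec.depth * level
        # terminators inside this unit, in transcription order
        inside = [
            (t, rt)
            for t, rt in terminators
            if t.strand == strand and start <= t.start and t.end <= end
        ]
        inside.sort(key=lambda p: p[0].start, reverse=(strand == "-"))
        cum = 1.0
        for t, rt in inside:
            if not 0 < rt <= 1:
                raise ValueError(f"{t.id}: readthrough must be in (0, 1]")
            cum *= rt
            if strand == "+":
                arr[t.end : end] = spec.depth * level * cum
            else:
                arr[start - 1 : t.start - 1] = spec.depth * level * cum

    for t, _ in terminators:
        in_unit = any(
            st == t.strand and s <= t.start and t.end <= e for s, e, st, _ in units
        )
        if not in_unit:
            raise ValueError(f"{t.id}: terminator not inside a same-strand unit")

    rng = np.random.default_rng(spec.seed)
    counts = {
        "sense": rng.poisson(expected["sense"]).astype(float),
        "antisense": rng.poisson(expected["antisense"]).astype(float),
    }
    counts["truth"] = {
        "expected": expected,
        "readthrough": {t.id: rt for t, rt in terminators},
    }
    return counts


def gen_fixture_circuits() -> dict[str, TruthTable]:
    """Named benchmark truth tables: a 2-input AND and three-input tables
    identified by hex code (most-significant-row-first)."""
    return {
        "AND2": TruthTable(2, (0, 0, 0, 1)),
        "0x08": TruthTable.from_hex("0x08", 3),
        "0xF1": TruthTable.from_hex("0xF1", 3),
        "0x0B": TruthTable.from_hex("0x0B", 3),
    }


def gen_inducer_grid(levels_a, levels_b) -> pd.DataFrame:
    """Full-factorial two-inducer design, row-major (a outer, b inner)."""
    la, lb = list(levels_a), list(levels_b)
    if not la or not lb:
        raise ValueError("inducer levels must be non-empty")
    rows = [{"inducer_a": a, "inducer_b": b} for a, b in itertools.product(la, lb)]
    return pd.DataFrame(rows)
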