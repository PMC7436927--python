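"""Measurement quantitation: RPU normalization, unit conversion, Hill and
growth-line fitting.

Promoter activity is the signal carrier of transcriptional circuits.  Raw
cytometry fluorescence is converted to relative promoter units against a
genome-integrated constitutive reference (RPU_G), which can then be mapped
to plasmid-referenced RPU or to absolute RNA-polymerase flux (RNAP/s)
through the library's conversion constants.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .library import ConversionConstants, GrowthLine, HillParams


class Unit(str, enum.Enum):
    RPU_G = "RPU_G"
    RPU = "RPU"
    RNAP_PER_S = "RNAP_per_s"


@dataclass(frozen=True)
class PromoterActivity:
    value: float
    unit: Unit = Unit.RPU_G

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("promoter activity must be >= 0")


class UnitError(ValueError):
    """Operation applied to an activity carrying the wrong unit tag."""


class ClippedNegativeWarning(UserWarning):
    """Background-subtracted activity was negative and clipped to zero."""


@dataclass
class CytometrySample:
    """A pre-gated population of single-cell fluorescence events for one
    condition and channel (arbitrary units)."""

    events: np.ndarray
    channel: str = "FITC-A"
    condition: str = ""

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.size == 0:
            raise ValueError("cytometry sample has no events")
        if not np.all(np.isfinite(self.events)):
            raise ValueError("cytometry sample contains non-finite values")


@dataclass(frozen=True)
class GrowthMeasurement:
    od_sample: float
    od_blank: float
    od_reference: float

    def __post_init__(self) -> None:
        if self.od_reference <= self.od_blank:
            raise ValueError("degenerate reference: od_reference must exceed od_blank")


def summarize_sample(
    sample: CytometrySample,
    stat: str = "median",
    floor: float | None = None,
) -> float:
    """Summarize a cytometry population by its median or geometric mean.

    The median (lower-median convention for even counts) represents gate and
    circuit expression levels; the geometric mean is used in the
    two-reporter terminator assay.  ``floor`` optionally clips events from
    below before the geometric mean (autofluorescence-subtracted events can
    dip to zero or below).
    """
    ev = sample.events
    if floor is not None:
        ev = np.maximum(ev, floor)
    if stat == "median":
        # lower median: element at index (n-1)//2 of the sorted events
        return float(np.sort(ev)[(ev.size - 1) // 2])
    if stat == "geometric_mean":
        if np.any(ev <= 0):
            raise ValueError(
                "geometric mean requires positive events; configure a floor"
            )
        return float(np.exp(np.mean(np.log(ev))))
    raise ValueError(f"unknown statistic {stat!r}")


def to_rpu(
    yfp_measured: float, yfp_blank: float, yfp_rpu_ref: float
) -> PromoterActivity:
    """Convert fluorescence (a.u.) to RPU_G against the reference promoter.

    activity = (measured - blank) / (reference - blank)

    ``blank`` is the autofluorescence of the wild-type host.  Negative
    results (measurement noise below autofluorescence) are clipped to 0
    with a :class:`ClippedNegativeWarning`.
    """
    if yfp_rpu_ref <= yfp_blank:
        raise ValueError("degenerate reference: reference must exceed blank")
    value = (yfp_measured - yfp_blank) / (yfp_rpu_ref - yfp_blank)
    if value < 0:
        warnings.warn(
            f"negative background-subtracted activity ({value:.3g}) clipped to 0",
            ClippedNegativeWarning,
            stacklevel=2,
        )
        value = 0.0
    return PromoterActivity(value, Unit.RPU_G)


def rpu_to_flux(
    a: PromoterActivity, c: ConversionConstants = ConversionConstants()
) -> PromoterActivity:
    """RPU_G -> absolute RNAP flux (RNAP/s), accounting for the effective
    copy number of the genomic landing-pad site:
    flux = activity * (RNAP/s per RPU per DNA) * copy number."""
    if a.unit is not Unit.RPU_G:
        raise UnitError(f"expected RPU_G, got {a.unit.value}")
    return PromoterActivity(
        a.value * c.flux_per_rpu_per_dna * c.landing_pad_copy_number, Unit.RNAP_PER_S
    )


def rpug_to_rpu(
    a: PromoterActivity, c: ConversionConstants = ConversionConstants()
) -> PromoterActivity:
    """Genome-referenced RPU_G -> plasmid-referenced RPU (divide by the
    calibrated divisor, default 6.33)."""
    if a.unit is not Unit.RPU_G:
        raise UnitError(f"expected RPU_G, got {a.unit.value}")
    return PromoterActivity(a.value / c.rpug_per_rpu, Unit.RPU)


def hill_response(p: HillParams, x) -> "float | np.ndarray":
    """Repression Hill function y = y_min + (y_max - y_min)/(1 + (x/K)^n).

    Strictly decreasing in x for n > 0; y(0) = y_max, y(inf) -> y_min.
    Accepts scalars or arrays (RPU_G in, RPU_G out).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("input activity must be >= 0")
    y = p.y_min + (p.y_max - p.y_min) / (1.0 + (x / p.K) ** p.n)
    return float(y) if y.ndim == 0 else y


@dataclass(frozen=True)
class HillFit:
    params: HillParams
    residual_norm: float
    converged: bool


# bounds of the fit: y_min > 0, span = y_max - y_min > 0, K > 0, n in (0.5, 8]
_LOWER = np.array([1e-9, 1e-9, 1e-12, 0.5])
_UPPER = np.array([np.inf, np.inf, np.inf, 8.0])


def _hill_log_residuals(theta: np.ndarray, x: np.ndarray, logy: np.ndarray) -> np.ndarray:
    y_min, span, K, n = theta
    model = y_min + span / (1.0 + (x / K) ** n)
    return np.log10(model) - logy


def fit_hill(x, y) -> HillFit:
    """Fit the four-parameter repression Hill function by least squares in
    log10 output space.

    Fitting in log space weights the OFF-state decade comparably to the ON
    state, which matters because y_min is typically two orders of magnitude
    below y_max.  Five deterministic starting points derived from the data
    guard against local minima; the best candidate is returned with a
    convergence flag (a flag of False means the response was degenerate or
    no start converged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.unique(x).size < 5:
        raise ValueError("need >= 5 distinct input activities")
    xp = x[x > 0]
    if xp.size == 0 or xp.max() / xp.min() < 10:
        raise ValueError("input activities must span at least one decade")
    if np.any(y <= 0):
        raise ValueError("all output activities must be positive")

    logy = np.log10(y)
    ymin0 = float(np.min(y))
    ymax0 = float(np.max(y))
    span0 = max(ymax0 - ymin0, 1e-9)
    gmx = float(np.exp(np.mean(np.log(xp))))
    # x value where y crosses mid-range: a robust K heuristic
    mid = ymin0 + span0 / 2.0
    order = np.argsort(x)
    below = y[order] < mid
    k_half = float(x[order][np.argmax(below)]) if below.any() and not below.all() else gmx
    k_half = k_half if k_half > 0 else gmx

    starts = [
        (ymin0, span0, k_half, 2.0),
        (0.5 * ymin0, span0, gmx, 1.0),
        (ymin0, span0, gmx, 4.0),
        (0.8 * ymin0, 1.2 * span0, k_half, 1.5),
        (ymin0, span0, k_half, 6.0),
    ]
    best = None
    for s in starts:
        theta0 = np.clip(np.array(s, dtype=float), _LOWER, _UPPER)
        try:
            res = least_squares(
                _hill_log_residuals,
                theta0,
                bounds=(_LOWER, _UPPER),
                args=(x, logy),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all Hill fit starts failed")

    y_min, span, K, n = best.x
    params = HillParams(y_max=y_min + span, y_min=y_min, K=K, n=n)
    # degenerate response (no measurable dynamic range) or n pinned at a
    # bound is flagged as non-converged; the best candidate is still returned
    converged = bool(
        best.success
        and span / (y_min + span) > 1e-3
        and n > 0.5 + 1e-6
        and n < 8.0 - 1e-6
    )
    return HillFit(params=params, residual_norm=float(np.sqrt(2 * best.cost)), converged=converged)


def fit_growth(x, od) -> GrowthLine:
    """Ordinary least-squares line of relative OD600 versus gate input."""
    x = np.asarray(x, dtype=float)
    od = np.asarray(od, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("all input activities identical; slope is unidentifiable")
    slope, intercept = np.polyfit(x, od, 1)
    return GrowthLine(intercept=float(intercept), slope=float(slope))


def relative_growth(g: GrowthMeasurement) -> float:
    """Blank-corrected growth relative to a reference strain:
    (od_sample - od_blank) / (od_reference - od_blank)."""
    return (g.od_sample - g.od_blank) / (g.od_reference - g.od_blank)
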