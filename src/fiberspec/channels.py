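"""Biomarker state, per-sensor response curves, and channel geometry.

The system multiplexes six fluorescent sensors on one fiber bundle, read
out with three excitation lasers:

* 405 nm — pH, dissolved oxygen (DO), glucose
* 488 nm — sodium, temperature
* 520 nm — calcium

Each sensor's steady-state calibration is expressed as a dimensionless
intensity ratio R(c) = I/I0, normalized to exactly 1 at the channel's
reference condition.  Quenched channels (temperature, DO) follow a
Stern-Volmer law linear in I0/I; sodium is linear in I/I0; pH, glucose and
calcium follow four-parameter logistic (sigmoid) binding curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigError, RangeError

#: Canonical biomarker order used everywhere (labels, arrays, reports).
BIOMARKERS: Tuple[str, ...] = (
    "temperature",
    "dissolved_oxygen",
    "pH",
    "sodium",
    "calcium",
    "glucose",
)

#: Short label codes used in CSV/JSON label columns.
LABEL_CODES: Dict[str, str] = {
    "temperature": "T",
    "dissolved_oxygen": "DO",
    "pH": "pH",
    "sodium": "Na",
    "calcium": "Ca",
    "glucose": "Glu",
}

#: Admissible simulator ranges (units: degC, mg/L, pH, mmol/L, mmol/L, mmol/L).
STATE_RANGES: Dict[str, Tuple[float, float]] = {
    "temperature": (33.0, 42.0),
    "dissolved_oxygen": (0.0, 8.0),
    "pH": (6.0, 8.0),
    "sodium": (0.0, 200.0),
    "calcium": (0.0, 3.0),
    "glucose": (0.0, 6.0),
}

#: Pixels per laser segment; merged vectors are [405 | 488 | 520].
SEGMENT_LENGTH = 460
MERGED_LENGTH = 3 * SEGMENT_LENGTH
LASERS: Tuple[int, ...] = (405, 488, 520)
LASER_SEGMENTS: Dict[int, Tuple[int, int]] = {
    405: (0, 460),
    488: (460, 920),
    520: (920, 1380),
}

#: Laser assignment of the six sensing channels.
CHANNEL_LASER: Dict[str, int] = {
    "pH": 405,
    "dissolved_oxygen": 405,
    "glucose": 405,
    "sodium": 488,
    "temperature": 488,
    "calcium": 520,
}

#: Default peak positions in the merged 1380-point vector (0-based).
DEFAULT_PEAK_INDEX: Dict[str, int] = {
    "pH": 34,
    "glucose": 28,
    "dissolved_oxygen": 341,
    "sodium": 725,
    "temperature": 884,
    "calcium": 1262,
}

#: Default photobleaching time constants, abstract exposure-time units.
DEFAULT_TAU: Dict[str, float] = {
    "temperature": 51.13,
    "dissolved_oxygen": 48.8,
    "pH": 37.0,
    "sodium": 22.0,
    "calcium": 38.0,
    "glucose": 133.7,
}

#: Seconds of accumulated laser on-time per abstract exposure-time unit.
DEFAULT_EXPOSURE_UNIT_S = 60.0

#: Physiological window over which the calcium sensitivity is quoted, and the
#: sweep resolution at which its slope is defined.
CALCIUM_WINDOW = (1.0, 1.35)
CALCIUM_WINDOW_STEP = 0.1


@dataclass(frozen=True)
class BiomarkerState:
    """The six true (or estimated) biomarker values with fixed units.

    temperature degC | dissolved_oxygen mg/L | pH | sodium mmol/L |
    calcium mmol/L | glucose mmol/L
    """

    temperature: float = 37.0
    dissolved_oxygen: float = 6.0
    pH: float = 7.35
    sodium: float = 145.0
    calcium: float = 1.2
    glucose: float = 3.3

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, b) for b in BIOMARKERS], dtype=float)

    @classmethod
    def from_array(cls, values) -> "BiomarkerState":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(BIOMARKERS),):
            raise ValueError(f"expected {len(BIOMARKERS)} values, got {values.shape}")
        return cls(**dict(zip(BIOMARKERS, values)))

    def replace(self, **kwargs) -> "BiomarkerState":
        return replace(self, **kwargs)

    def validate(self, clip: bool = False) -> "BiomarkerState":
        """Check (or clip to) the simulator's admissible ranges."""
        out = {}
        for name in BIOMARKERS:
            lo, hi = STATE_RANGES[name]
            v = float(getattr(self, name))
            if not lo <= v <= hi:
                if not clip:
                    raise RangeError(
                        f"{name}={v} outside admissible range [{lo}, {hi}]"
                    )
                v = min(max(v, lo), hi)
            out[name] = v
        return BiomarkerState(**out)


#: Healthy-CSF reference state used by scenario presets.
HEALTHY_STATE = BiomarkerState()


@dataclass(frozen=True)
class ResponseParams:
    """Parameters of one channel's intensity-ratio calibration curve.

    ``family`` is one of:

    * ``linear_ratio`` — I/I0 = 1 + slope * (c - reference)
    * ``stern_volmer`` — I0/I = 1 + k_sv * (c - reference); evaluate()
      returns the emitted ratio I/I0 = 1 / (I0/I)
    * ``logistic4``    — I/I0 = A + (B - A) / (1 + exp(-k (c - c0)))

    ``evaluate`` always returns the emitted relative intensity I/I0, which
    equals exactly 1 at ``reference_condition``.
    """

    family: str
    parameters: Dict[str, float]
    reference_condition: float
    valid_range: Tuple[float, float]

    def evaluate(self, c) -> np.ndarray | float:
        c = np.asarray(c, dtype=float)
        p = self.parameters
        if self.family == "linear_ratio":
            r = 1.0 + p["slope"] * (c - self.reference_condition)
        elif self.family == "stern_volmer":
            r = 1.0 / (1.0 + p["k_sv"] * (c - self.reference_condition))
        elif self.family == "logistic4":
            a, b, k, c0 = p["A"], p["B"], p["k"], p["c0"]
            r = a + (b - a) / (1.0 + np.exp(-k * (c - c0)))
        else:
            raise ConfigError(f"unknown response family {self.family!r}")
        return float(r) if r.ndim == 0 else r

    def invert(self, ratio: float) -> float:
        """Unique concentration with evaluate(c) == ratio (closed form)."""
        p = self.parameters
        lo, hi = self.attainable_range()
        if not (min(lo, hi) - 1e-12 <= ratio <= max(lo, hi) + 1e-12):
            raise RangeError(
                f"ratio {ratio:.6g} outside attainable range "
                f"[{min(lo, hi):.6g}, {max(lo, hi):.6g}]; nearest bound is "
                f"{min(max(ratio, min(lo, hi)), max(lo, hi)):.6g}"
            )
        ratio = min(max(ratio, min(lo, hi)), max(lo, hi))
        if self.family == "linear_ratio":
            return self.reference_condition + (ratio - 1.0) / p["slope"]
        if self.family == "stern_volmer":
            return self.reference_condition + (1.0 / ratio - 1.0) / p["k_sv"]
        if self.family == "logistic4":
            a, b, k, c0 = p["A"], p["B"], p["k"], p["c0"]
            y = (ratio - a) / (b - a)
            y = min(max(y, 1e-15), 1.0 - 1e-15)
            return c0 - math.log(1.0 / y - 1.0) / k
        raise ConfigError(f"unknown response family {self.family!r}")

    def attainable_range(self) -> Tuple[float, float]:
        """Ratio values at the two ends of valid_range (any orientation)."""
        lo, hi = self.valid_range
        return float(self.evaluate(lo)), float(self.evaluate(hi))

    def midpoint_slope(self) -> float:
        """d(ratio)/dc at the logistic midpoint (logistic4 only)."""
        if self.family != "logistic4":
            raise ConfigError("midpoint_slope is defined for logistic4 only")
        p = self.parameters
        return (p["B"] - p["A"]) * p["k"] / 4.0


@dataclass(frozen=True)
class SensorChannel:
    """One fluorescent sensing channel on the bundle."""

    name: str
    excitation_nm: int
    merged_peak_index: int
    response: ResponseParams
    tau: float
    peak_fwhm: float = 30.0
    cross_temperature_coeff: float = 0.005
    base_amplitude: float = 1000.0

    def __post_init__(self):
        if self.name not in BIOMARKERS:
            raise ConfigError(f"unknown channel name {self.name!r}")
        if self.excitation_nm != CHANNEL_LASER[self.name]:
            raise ConfigError(
                f"channel {self.name} must use the "
                f"{CHANNEL_LASER[self.name]} nm laser, got {self.excitation_nm}"
            )
        lo, hi = LASER_SEGMENTS[self.excitation_nm]
        if not lo <= self.merged_peak_index < hi:
            raise ConfigError(
                f"merged_peak_index {self.merged_peak_index} outside the "
                f"{self.excitation_nm} nm segment [{lo}, {hi})"
            )
        if self.tau <= 0:
            raise ConfigError("tau must be positive")
        if self.cross_temperature_coeff < 0:
            raise ConfigError("cross_temperature_coeff must be >= 0")

    @property
    def segment_pixel(self) -> int:
        """Peak position within its own 460-pixel laser segment."""
        return self.merged_peak_index % SEGMENT_LENGTH


def evaluate_response(channel: SensorChannel, state: BiomarkerState,
                      clip: bool = False) -> float:
    """Relative emitted intensity I/I0 of ``channel`` at ``state``.

    Quenched channels (temperature, DO) return 1/(I0/I).  The channel's
    reference condition maps to exactly 1.  Values outside the response's
    valid range raise :class:`RangeError` unless ``clip`` is set.
    """
    c = float(getattr(state, channel.name))
    lo, hi = channel.response.valid_range
    if not lo <= c <= hi:
        if not clip:
            raise RangeError(
                f"{channel.name}={c} outside valid range [{lo}, {hi}]"
            )
        c = min(max(c, lo), hi)
    return float(channel.response.evaluate(c))


def _solve_ph_response() -> ResponseParams:
    # Steepness k solves k/tanh(k/2) = 2.624 (midpoint slope), then the
    # amplitudes honor R(6) = 1 and R(8) = 5 (the 5x rise from pH 6 to 8).
    target = 2.624
    k = brentq(lambda k: k / math.tanh(k / 2.0) - target, 0.05, 10.0,
               xtol=1e-14)
    span = 4.0 / math.tanh(k / 2.0)          # B - A from R(8) - R(6) = 4
    f6 = 1.0 / (1.0 + math.exp(-k * (6.0 - 7.0)))
    a = 1.0 - span * f6
    return ResponseParams(
        family="logistic4",
        parameters={"A": a, "B": a + span, "k": k, "c0": 7.0},
        reference_condition=6.0,
        valid_range=(6.0, 8.0),
    )


def _solve_glucose_response() -> ResponseParams:
    # Midpoint 3.0 mmol/L (center of the 0-6 range), unit steepness; the
    # amplitudes honor R(0) = 1 and the 4-fold rise R(5) = 4 R(1).
    k, c0 = 1.0, 3.0
    f = lambda c: 1.0 / (1.0 + math.exp(-k * (c - c0)))
    span = 1.0 / (f(0.0) + (f(5.0) - 4.0 * f(1.0)) / 3.0)
    a = 1.0 - span * f(0.0)
    return ResponseParams(
        family="logistic4",
        parameters={"A": a, "B": a + span, "k": k, "c0": c0},
        reference_condition=0.0,
        valid_range=(0.0, 6.0),
    )


def _solve_calcium_response() -> ResponseParams:
    # Midpoint 0.5 mmol/L (indicator Kd); k chosen so the curve saturates
    # smoothly above 2 mmol/L; amplitude solved so the least-squares slope
    # of I/I0 over the physiological window, sampled at the characterization
    # sweep resolution, is 0.41 per mmol/L.  R(0) = 1.
    k, c0 = 3.0, 0.5
    grid = np.arange(CALCIUM_WINDOW[0], CALCIUM_WINDOW[1] + 1e-9,
                     CALCIUM_WINDOW_STEP)
    f = 1.0 / (1.0 + np.exp(-k * (grid - c0)))
    slope_f = np.polyfit(grid, f, 1)[0]
    span = 0.41 / slope_f
    f0 = 1.0 / (1.0 + math.exp(-k * (0.0 - c0)))
    a = 1.0 - span * f0
    return ResponseParams(
        family="logistic4",
        parameters={"A": a, "B": a + span, "k": k, "c0": c0},
        reference_condition=0.0,
        valid_range=(0.0, 3.0),
    )


def default_channels() -> Dict[str, SensorChannel]:
    """The six default channels with the characterized sensitivities."""
    responses = {
        "temperature": ResponseParams(
            family="stern_volmer",
            parameters={"k_sv": 0.04},
            reference_condition=33.0,
            valid_range=(33.0, 42.0),
        ),
        "dissolved_oxygen": ResponseParams(
            family="stern_volmer",
            parameters={"k_sv": 0.38},
            reference_condition=0.0,
            valid_range=(0.0, 8.0),
        ),
        "pH": _solve_ph_response(),
        "sodium": ResponseParams(
            family="linear_ratio",
            parameters={"slope": 0.0064},
            reference_condition=0.0,
            valid_range=(0.0, 200.0),
        ),
        "calcium": _solve_calcium_response(),
        "glucose": _solve_glucose_response(),
    }
    channels = {}
    for name in BIOMARKERS:
        channels[name] = SensorChannel(
            name=name,
            excitation_nm=CHANNEL_LASER[name],
            merged_peak_index=DEFAULT_PEAK_INDEX[name],
            response=responses[name],
            tau=DEFAULT_TAU[name],
            cross_temperature_coeff=0.0 if name == "temperature" else 0.005,
        )
    return channels
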