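"""Calibration: response-curve fitting, two-standard session correction.

Two layers of calibration exist in the system:

* **Characterization** — per-channel response curves fitted to a sweep of
  standard buffer concentrations (:func:`fit_linear_ratio`,
  :func:`fit_logistic4`), yielding the stored :class:`CalibrationModel`.
* **Session correction** — before each measurement session, two standard
  buffers of known composition are measured; per channel an affine
  intensity correction (reference intensity + offset) is solved so that
  inverting the response curve reproduces both standards exactly
  (:func:`two_point_calibrate`).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .channels import (
    BIOMARKERS,
    DEFAULT_TAU,
    BiomarkerState,
    ResponseParams,
    SensorChannel,
    default_channels,
)
from .errors import FitError, InputError, RangeError
from .features import FeatureVector

SCHEMA_VERSION = 1

#: Default low/high artificial-CSF standards (T, DO, pH, Na, Ca, glucose).
DEFAULT_STANDARD_LOW = BiomarkerState(
    temperature=34.0, dissolved_oxygen=2.0, pH=6.5, sodium=40.0,
    calcium=0.4, glucose=1.0)
DEFAULT_STANDARD_HIGH = BiomarkerState(
    temperature=40.0, dissolved_oxygen=7.0, pH=7.8, sodium=160.0,
    calcium=1.6, glucose=5.0)


@dataclass
class ChannelCalibration:
    """Fitted response and session correction of one channel."""

    response: ResponseParams
    fit_r2: float = float("nan")
    tau: float = 1.0
    reference_intensity: float = 1.0   # intensity units per unit ratio
    offset: float = 0.0                # intensity offset (two-point)

    def ratio_from_intensity(self, intensity: float) -> float:
        """Standardized I/I0 ratio of a corrected feature height."""
        return (intensity - self.offset) / self.reference_intensity

    def concentration_from_intensity(self, intensity: float) -> float:
        return self.response.invert(self.ratio_from_intensity(intensity))


@dataclass
class CalibrationModel:
    """All six channels' calibrations plus provenance."""

    channels: Dict[str, ChannelCalibration]
    created_at: float = field(default_factory=time.time)
    source: str = "default"

    def taus(self) -> Dict[str, float]:
        return {name: cc.tau for name, cc in self.channels.items()}

    # ---- persistence (versioned JSON) ------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "created_at": self.created_at,
            "source": self.source,
            "channels": {
                name: {
                    "family": cc.response.family,
                    "parameters": dict(cc.response.parameters),
                    "reference_condition": cc.response.reference_condition,
                    "valid_range": list(cc.response.valid_range),
                    "fit_r2": cc.fit_r2,
                    "tau": cc.tau,
                    "reference_intensity": cc.reference_intensity,
                    "offset": cc.offset,
                }
                for name, cc in self.channels.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CalibrationModel":
        if data.get("schema_version") != SCHEMA_VERSION:
            raise InputError(
                f"unsupported calibration schema {data.get('schema_version')}")
        channels = {}
        for name, d in data["channels"].items():
            channels[name] = ChannelCalibration(
                response=ResponseParams(
                    family=d["family"],
                    parameters=dict(d["parameters"]),
                    reference_condition=d["reference_condition"],
                    valid_range=tuple(d["valid_range"]),
                ),
                fit_r2=d["fit_r2"],
                tau=d["tau"],
                reference_intensity=d["reference_intensity"],
                offset=d["offset"],
            )
        return cls(channels=channels, created_at=data["created_at"],
                   source=data["source"])

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_calibration_model(
        channels: Optional[Dict[str, SensorChannel]] = None,
        reference_intensities: Optional[Dict[str, float]] = None
        ) -> CalibrationModel:
    """Nominal model: configured responses, unit-free gains.

    ``reference_intensities`` defaults to each channel's base amplitude, so
    a noiseless unbleached reference-condition peak maps to ratio 1.
    """
    channels = channels or default_channels()
    cal = {}
    for name, ch in channels.items():
        ref = (reference_intensities or {}).get(name, ch.base_amplitude)
        cal[name] = ChannelCalibration(response=ch.response, fit_r2=1.0,
                                       tau=ch.tau, reference_intensity=ref)
    return CalibrationModel(channels=cal, source="configured")


def fit_linear_ratio(concentrations: Sequence[float],
                     ratios: Sequence[float]
                     ) -> Tuple[float, float, float]:
    """OLS line through (concentration, ratio): (slope, intercept, R^2)."""
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if c.size != r.size or c.size < 2:
        raise InputError("need >= 2 (concentration, ratio) pairs")
    if np.allclose(c, c[0]):
        raise FitError("all concentrations identical; line is undefined")
    slope, intercept = np.polyfit(c, r, 1)
    fitted = slope * c + intercept
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - float(np.sum((r - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def _logistic4(c, a, b, k, c0):
    return a + (b - a) / (1.0 + np.exp(-k * (c - c0)))


def fit_logistic4(concentrations: Sequence[float], ratios: Sequence[float],
                  midpoint_hint: Optional[float] = None
                  ) -> Tuple[float, float, float, float, float]:
    """Nonlinear least-squares 4-parameter logistic fit.

    Returns (A, B, k, c0, R^2).  Orientation is encoded in the sign of k
    (monotone-decreasing data yield k < 0).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if c.size != r.size or c.size < 5:
        raise InputError("need >= 5 points spanning the transition")
    c0_hint = midpoint_hint if midpoint_hint is not None else float(np.median(c))
    span = c.max() - c.min()
    increasing = r[np.argmax(c)] >= r[np.argmin(c)]
    k0 = (4.0 / span) if increasing else (-4.0 / span)
    p0 = (float(r.min()), float(r.max()), k0, c0_hint)
    try:
        popt, _ = curve_fit(_logistic4, c, r, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise FitError(f"logistic4 fit did not converge: {exc}") from exc
    fitted = _logistic4(c, *popt)
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - float(np.sum((r - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    a, b, k, c0 = (float(v) for v in popt)
    return a, b, k, c0, r2


def invert_response(channel: SensorChannel | ResponseParams,
                    ratio: float) -> float:
    """Concentration whose response equals ``ratio`` (closed form)."""
    response = channel.response if isinstance(channel, SensorChannel) \
        else channel
    return response.invert(ratio)


def two_point_calibrate(measured_features: Tuple[FeatureVector, FeatureVector],
                        expected_states: Tuple[BiomarkerState, BiomarkerState],
                        model: CalibrationModel) -> CalibrationModel:
    """Session correction from two measured standard buffers.

    Per channel, solves the affine pair (reference_intensity, offset) so
    that ``concentration_from_intensity`` reproduces both expected
    concentrations exactly at the two standards.  For a pure laser-power
    (gain) perturbation the offset solves to ~0 and the correction is the
    spec's multiplicative gain.
    """
    fv1, fv2 = measured_features
    s1, s2 = expected_states
    if fv1.corrected is not fv2.corrected:
        raise InputError("both standards must share correction state")
    corrected = {}
    for name, cc in model.channels.items():
        c1 = float(getattr(s1, name))
        c2 = float(getattr(s2, name))
        if np.isclose(c1, c2):
            raise RangeError(
                f"identical standards for channel {name!r} ({c1}); "
                "two-point calibration is underdetermined")
        h1 = fv1.peaks[name].height
        h2 = fv2.peaks[name].height
        r1 = float(cc.response.evaluate(c1))
        r2 = float(cc.response.evaluate(c2))
        # h = reference_intensity * R(c) + offset at both standards
        ref = (h1 - h2) / (r1 - r2)
        if ref <= 0:
            raise FitError(
                f"non-positive reference intensity for channel {name!r}; "
                "measured standards are inconsistent with the response")
        offset = h1 - ref * r1
        corrected[name] = ChannelCalibration(
            response=cc.response, fit_r2=cc.fit_r2, tau=cc.tau,
            reference_intensity=ref, offset=offset)
    return CalibrationModel(channels=corrected, source=model.source)


def fit_calibration_model(
        sweeps: Dict[str, Tuple[Sequence[float], Sequence[float]]],
        channels: Optional[Dict[str, SensorChannel]] = None
        ) -> CalibrationModel:
    """Fit every channel's response from (concentration, I/I0-ratio) sweeps.

    Linear-family channels are fitted with OLS (Stern-Volmer channels on
    I0/I = 1/ratio); logistic channels with :func:`fit_logistic4`.
    """
    channels = channels or default_channels()
    out = {}
    for name, ch in channels.items():
        conc, ratios = sweeps[name]
        conc = np.asarray(conc, dtype=float)
        ratios = np.asarray(ratios, dtype=float)
        if ch.response.family == "stern_volmer":
            slope, intercept, r2 = fit_linear_ratio(conc, 1.0 / ratios)
            params = ResponseParams(
                family="stern_volmer", parameters={"k_sv": float(slope)},
                reference_condition=float((1.0 - intercept) / slope)
                if slope else 0.0,
                valid_range=ch.response.valid_range)
        elif ch.response.family == "linear_ratio":
            slope, intercept, r2 = fit_linear_ratio(conc, ratios)
            params = ResponseParams(
                family="linear_ratio", parameters={"slope": float(slope)},
                reference_condition=float((1.0 - intercept) / slope)
                if slope else 0.0,
                valid_range=ch.response.valid_range)
        else:
            a, b, k, c0, r2 = fit_logistic4(
                conc, ratios,
                midpoint_hint=ch.response.parameters.get("c0"))
            params = ResponseParams(
                family="logistic4",
                parameters={"A": a, "B": b, "k": k, "c0": c0},
                reference_condition=ch.response.reference_condition,
                valid_range=ch.response.valid_range)
        out[name] = ChannelCalibration(response=params, fit_r2=r2,
                                       tau=ch.tau,
                                       reference_intensity=ch.base_amplitude)
    return CalibrationModel(channels=out, source="fitted-sweep")
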