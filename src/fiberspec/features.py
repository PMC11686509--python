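"""Spectral feature extraction, photobleaching compensation, selection.

Five features are extracted per channel from the baseline-corrected merged
spectrum: peak height, full width at half prominence, trapezoidal area
between the flanking local minima, peak position, and prominence.  Heights
are read at the channel's fixed nominal index (the six characterized peak
pixels); peak geometry (position, width, area, prominence) is anchored at
the local maximum located within ``search_radius`` of that index.

Photobleaching follows I_f(t) = I_f0 exp(-t/tau); correcting a feature
vector multiplies height, area and prominence by exp(t/tau) while width and
position — invariant under amplitude scaling of a Lorentzian — are left
untouched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import argrelextrema

from .channels import (
    BIOMARKERS,
    DEFAULT_EXPOSURE_UNIT_S,
    LASERS,
    LASER_SEGMENTS,
    BiomarkerState,
    SensorChannel,
)
from .errors import ConfigError, InputError, ParameterError, StateError
from .preprocess import MergedSpectrum

#: Per-channel feature kinds, in canonical column order.
FEATURE_KINDS: Tuple[str, ...] = (
    "height", "width", "area", "position", "prominence")


@dataclass
class PeakFeatures:
    """Features of one channel's peak in one scan."""

    height: float
    width: float
    area: float
    position: int
    prominence: float
    located: bool = True
    clipped: bool = False


@dataclass
class FeatureVector:
    """Per-channel peak features of one scan, before/after bleach correction.

    ``exposures`` maps channel name -> exposure in abstract units (seconds
    of on-time divided by the exposure unit), the ``t`` entering the
    exp(t/tau) compensation.
    """

    peaks: Dict[str, PeakFeatures]
    exposures: Dict[str, float]
    timestamp: float = 0.0
    label: Optional[BiomarkerState] = None
    corrected: bool = False


def _local_extrema(segment: np.ndarray, comparator) -> np.ndarray:
    idx = argrelextrema(segment, comparator, order=1)[0]
    return idx


def _flanking_minima(segment: np.ndarray, peak: int) -> Tuple[int, int]:
    """Nearest local minima on each side of ``peak`` (segment edges if none)."""
    minima = _local_extrema(segment, np.less_equal)
    left = minima[minima < peak]
    right = minima[minima > peak]
    lo = int(left.max()) if left.size else 0
    hi = int(right.min()) if right.size else segment.size - 1
    return lo, hi


def _half_level_width(segment: np.ndarray, peak: int, level: float) -> float:
    """Interpolated full width of the peak at ``level`` (pixels)."""
    n = segment.size
    left = float(peak)
    for i in range(peak, 0, -1):
        if segment[i - 1] <= level:
            y1, y0 = segment[i], segment[i - 1]
            frac = (y1 - level) / (y1 - y0) if y1 != y0 else 0.0
            left = i - frac
            break
    else:
        left = 0.0
    right = float(peak)
    for i in range(peak, n - 1):
        if segment[i + 1] <= level:
            y1, y0 = segment[i], segment[i + 1]
            frac = (y1 - level) / (y1 - y0) if y1 != y0 else 0.0
            right = i + frac
            break
    else:
        right = float(n - 1)
    return right - left


def extract_channel(segment: np.ndarray, nominal_pixel: int,
                    search_radius: int = 15,
                    height_mode: str = "fixed") -> PeakFeatures:
    """Extract one channel's peak features from its laser segment."""
    if height_mode not in ("fixed", "located"):
        raise ParameterError(f"unknown height_mode {height_mode!r}")
    maxima = _local_extrema(segment, np.greater_equal)
    in_window = maxima[np.abs(maxima - nominal_pixel) <= search_radius]
    if in_window.size:
        peak = int(in_window[np.argmax(segment[in_window])])
        located = True
    else:
        peak = int(nominal_pixel)
        located = False
    lo, hi = _flanking_minima(segment, peak)
    peak_value = float(segment[peak])
    prominence = peak_value - max(float(segment[lo]), float(segment[hi]))
    area = float(np.trapezoid(segment[lo:hi + 1]))
    width = _half_level_width(segment, peak, peak_value - prominence / 2.0)
    height = float(segment[nominal_pixel]) if height_mode == "fixed" \
        else peak_value
    clipped = False
    if height < 0 or area < 0 or prominence < 0:
        clipped = True
        height, area, prominence = (max(height, 0.0), max(area, 0.0),
                                    max(prominence, 0.0))
    return PeakFeatures(height=height, width=width, area=area, position=peak,
                        prominence=prominence, located=located,
                        clipped=clipped)


def extract_features(merged: MergedSpectrum,
                     channels: Dict[str, SensorChannel],
                     search_radius: int = 15,
                     height_mode: str = "fixed",
                     exposure_unit_s: float = DEFAULT_EXPOSURE_UNIT_S
                     ) -> FeatureVector:
    """Extract all channels' peak features from a baseline-corrected scan."""
    peaks: Dict[str, PeakFeatures] = {}
    exposures: Dict[str, float] = {}
    for name, ch in channels.items():
        laser = ch.excitation_nm
        if laser not in LASER_SEGMENTS:
            raise InputError(f"channel {name} uses unknown laser {laser}")
        seg_lo, _ = LASER_SEGMENTS[laser]
        segment = merged.segment(laser)
        pf = extract_channel(segment, ch.merged_peak_index - seg_lo,
                             search_radius, height_mode)
        pf.position += seg_lo  # report merged-vector index
        peaks[name] = pf
        exposures[name] = merged.exposure_map.get(laser, 0.0) / exposure_unit_s
    return FeatureVector(peaks=peaks, exposures=exposures,
                         timestamp=merged.timestamp, label=merged.label)


def photobleach_correct(features: FeatureVector,
                        taus: Dict[str, float]) -> FeatureVector:
    """Rescale amplitude-like features back to their exposure-0 values.

    height, area and prominence are multiplied by exp(t/tau); width and
    position are exactly unchanged (Lorentzian shape is amplitude-scaled by
    bleaching).  Re-correcting an already corrected vector is an error.
    """
    if features.corrected:
        raise StateError("feature vector is already photobleach-corrected")
    new_peaks = {}
    for name, pf in features.peaks.items():
        if name not in taus:
            raise ConfigError(f"no tau configured for channel {name!r}")
        tau = taus[name]
        if tau <= 0:
            raise ConfigError(f"tau for {name} must be positive")
        gain = math.exp(features.exposures.get(name, 0.0) / tau)
        new_peaks[name] = replace(pf, height=pf.height * gain,
                                  area=pf.area * gain,
                                  prominence=pf.prominence * gain)
    return FeatureVector(peaks=new_peaks, exposures=dict(features.exposures),
                         timestamp=features.timestamp, label=features.label,
                         corrected=True)


def fit_tau(times: Sequence[float],
            intensities: Sequence[float]) -> Tuple[float, float]:
    """Least-squares fit of I(t) = I0 exp(-t/tau); returns (tau, R^2).

    A log-linear regression provides the starting point; nonlinear
    refinement then minimizes the residual in intensity space.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size != y.size:
        raise InputError("times and intensities must have equal length")
    if t.size < 3:
        raise InputError("fit_tau needs at least 3 points")
    if np.any(y <= 0):
        raise InputError("intensities must be positive")
    if np.allclose(y, y[0]) or np.allclose(t, t[0]):
        from .errors import FitError
        raise FitError("degenerate (constant) decay series")
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if slope >= 0:
        slope = -1.0 / (t.max() - t.min() + 1.0)
    tau0, i0 = -1.0 / slope, float(np.exp(intercept))
    popt, _ = curve_fit(lambda tt, i0_, tau_: i0_ * np.exp(-tt / tau_),
                        t, y, p0=(i0, tau0), maxfev=10000)
    fitted = popt[0] * np.exp(-t / popt[1])
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(popt[1]), r2


def pearson_select(feature_matrix: pd.DataFrame, labels: pd.DataFrame,
                   threshold: float = 0.5
                   ) -> Tuple[pd.Series, pd.DataFrame]:
    """Pearson-correlation feature selection against the six labels.

    Returns a boolean mask (feature selected iff max |r| over labels >=
    ``threshold``) and the full feature x label correlation table.
    Zero-variance features get r = 0 with a warning.
    """
    x = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise InputError("features and labels must have equal sample counts")
    if x.shape[0] < 3:
        raise InputError("pearson_select needs at least 3 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("features and labels must be finite")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc ** 2).mean(axis=0))
    sy = np.sqrt((yc ** 2).mean(axis=0))
    dead = sx == 0
    if dead.any():
        names = list(np.asarray(feature_matrix.columns)[dead])
        warnings.warn(f"zero-variance features (r set to 0): {names}",
                      RuntimeWarning, stacklevel=2)
    denom = np.outer(np.where(dead, 1.0, sx),
                     np.where(sy == 0, 1.0, sy))
    r = (xc.T @ yc) / x.shape[0] / denom
    r[dead, :] = 0.0
    r[:, sy == 0] = 0.0
    table = pd.DataFrame(r, index=feature_matrix.columns,
                         columns=labels.columns)
    mask = pd.Series(table.abs().max(axis=1) >= threshold,
                     index=feature_matrix.columns)
    return mask, table


def feature_frame(feature_vectors: Sequence[FeatureVector],
                  channels: Optional[Dict[str, SensorChannel]] = None,
                  with_labels: bool = True
                  ) -> Tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Tabulate feature vectors: columns ``{channel}_{kind}`` + exposures.

    Returns (features, labels); labels is None when any vector is unlabeled
    or ``with_labels`` is False.
    """
    names = list(channels) if channels else list(BIOMARKERS)
    rows, label_rows = [], []
    for fv in feature_vectors:
        row = {}
        for name in names:
            pf = fv.peaks[name]
            for kind in FEATURE_KINDS:
                row[f"{name}_{kind}"] = float(getattr(pf, kind))
        for name in names:
            row[f"exposure_{name}"] = fv.exposures.get(name, 0.0)
        rows.append(row)
        if fv.label is not None:
            label_rows.append({b: getattr(fv.label, b) for b in BIOMARKERS})
    features = pd.DataFrame(rows)
    labels = None
    if with_labels and len(label_rows) == len(rows) and rows:
        labels = pd.DataFrame(label_rows)
    return features, labels
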