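"""Preprocessing: smooth, baseline-correct, standardize, merge, label.

The pipeline order is fixed — denoise -> baseline_correct -> standardize ->
merge -> label — and :class:`PreprocessPipeline` enforces and records it.
Baseline removal uses asymmetric penalized least squares: a second-
difference-penalized weighted fit in which points above the running
baseline (peaks) carry weight ``p`` and points below carry ``1 - p``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.signal import savgol_filter

from .channels import (
    LASERS,
    LASER_SEGMENTS,
    MERGED_LENGTH,
    SEGMENT_LENGTH,
    BiomarkerState,
)
from .errors import CalibrationRequiredError, InputError, ParameterError
from .sim import Scan, SpectralFrame


@dataclass
class MergedSpectrum:
    """The 1380-point measurement vector [405 | 488 | 520] plus metadata."""

    intensities: np.ndarray
    exposure_map: Dict[int, float]
    timestamp: float = 0.0
    label: Optional[BiomarkerState] = None
    provenance: Tuple[str, ...] = ()

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (MERGED_LENGTH,):
            raise InputError(
                f"merged spectrum must have {MERGED_LENGTH} values, "
                f"got {self.intensities.shape}"
            )

    def segment(self, laser: int) -> np.ndarray:
        lo, hi = LASER_SEGMENTS[laser]
        return self.intensities[lo:hi]


def denoise(frame: SpectralFrame, window: int = 11,
            order: int = 3) -> SpectralFrame:
    """Moving-window polynomial (Savitzky-Golay) smoothing."""
    if window % 2 == 0:
        raise ParameterError("smoothing window must be odd")
    if not 3 <= window <= 101:
        raise ParameterError("smoothing window must be in [3, 101]")
    if order >= window:
        raise ParameterError("polynomial order must be < window")
    smoothed = savgol_filter(frame.intensities, window, order)
    return frame.copy_with(smoothed)


def asls_baseline(y: np.ndarray, lam: float = 1e8, p: float = 0.001,
                  niter: int = 10, tol: float = 1e-6) -> np.ndarray:
    """Asymmetric penalized least-squares baseline estimate.

    Iteratively solves (W + lam D'D) z = W y with the second-difference
    operator D, reweighting w_i = p where y_i > z_i and 1 - p otherwise.
    Emits a warning (and returns the last iterate) if the weights have not
    settled after ``niter`` iterations.
    """
    if lam <= 0:
        raise ParameterError("smoothness lambda must be > 0")
    if not 0.0 < p < 1.0:
        raise ParameterError("asymmetry p must lie in (0, 1)")
    y = np.asarray(y, dtype=float)
    n = y.size
    d = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (d.T @ d)
    w = np.ones(n)
    z = np.zeros(n)
    scale = max(float(np.max(np.abs(y))), 1.0)
    for _ in range(niter):
        mat = sp.diags(w, 0, format="csc") + penalty
        z_new = spsolve(mat, w * y)
        change = float(np.max(np.abs(z_new - z))) / scale
        z = z_new
        w = np.where(y > z, p, 1.0 - p)
        if change < tol:
            break
    else:
        warnings.warn("asls_baseline: baseline did not settle within "
                      f"{niter} iterations (last change {change:.2e})",
                      RuntimeWarning, stacklevel=2)
    return z


def baseline_correct(frame: SpectralFrame, lam: float = 1e8, p: float = 0.001,
                     niter: int = 10) -> SpectralFrame:
    """Subtract the asymmetric penalized least-squares baseline."""
    baseline = asls_baseline(frame.intensities, lam=lam, p=p, niter=niter)
    return frame.copy_with(frame.intensities - baseline)


def standardize(frame: SpectralFrame,
                reference: Optional[float]) -> SpectralFrame:
    """Divide by the stored per-laser calibration reference intensity.

    Makes spectra comparable across sessions/laser powers while preserving
    the ratio semantics the calibration curves rely on.
    """
    if reference is None:
        raise CalibrationRequiredError(
            f"no calibration reference stored for the "
            f"{frame.excitation_nm} nm laser"
        )
    if reference <= 0:
        raise ParameterError("calibration reference must be > 0")
    return frame.copy_with(frame.intensities / reference)


def merge(frames: Sequence[SpectralFrame],
          label_state: Optional[BiomarkerState] = None,
          provenance: Tuple[str, ...] = ()) -> MergedSpectrum:
    """Concatenate exactly one frame per laser in fixed [405|488|520] order."""
    by_laser: Dict[int, SpectralFrame] = {}
    for frame in frames:
        if frame.excitation_nm in by_laser:
            raise InputError(
                f"duplicate frame for the {frame.excitation_nm} nm laser")
        by_laser[frame.excitation_nm] = frame
    missing = [laser for laser in LASERS if laser not in by_laser]
    if missing:
        raise InputError(f"missing frames for lasers {missing}")
    intensities = np.concatenate(
        [by_laser[laser].intensities for laser in LASERS])
    exposure_map = {laser: by_laser[laser].cumulative_on_time
                    for laser in LASERS}
    timestamp = min(by_laser[laser].timestamp for laser in LASERS)
    return MergedSpectrum(intensities, exposure_map, timestamp,
                          label=label_state,
                          provenance=provenance + ("merge",))


def unmerge(merged: MergedSpectrum) -> Dict[int, SpectralFrame]:
    """Split a merged spectrum back into its three per-laser frames."""
    return {
        laser: SpectralFrame(laser, merged.segment(laser).copy(),
                             merged.exposure_map.get(laser, 0.0),
                             merged.timestamp)
        for laser in LASERS
    }


def label(merged: MergedSpectrum, state: BiomarkerState) -> MergedSpectrum:
    """Attach (or overwrite) the six-value ground-truth label."""
    merged.label = state
    if "label" not in merged.provenance:
        merged.provenance = merged.provenance + ("label",)
    return merged


@dataclass
class PreprocessPipeline:
    """Fixed-order preprocessing of one scan into a merged spectrum.

    ``references`` holds the per-laser calibration reference intensities
    used by the standardize step; when absent, standardization is skipped
    (raw intensity scale retained) unless ``require_reference`` is set.
    """

    window: int = 11
    order: int = 3
    lam: float = 1e8
    p: float = 0.001
    niter: int = 10
    references: Optional[Dict[int, float]] = None
    require_reference: bool = False

    def process_frame(self, frame: SpectralFrame) -> SpectralFrame:
        out = denoise(frame, self.window, self.order)
        out = baseline_correct(out, self.lam, self.p, self.niter)
        if self.references is not None:
            out = standardize(out, self.references.get(frame.excitation_nm))
        elif self.require_reference:
            raise CalibrationRequiredError(
                "pipeline requires calibration references")
        return out

    def process_scan(self, scan: Scan,
                     attach_label: bool = True) -> MergedSpectrum:
        steps = ["denoise", "baseline_correct"]
        if self.references is not None:
            steps.append("standardize")
        frames = [self.process_frame(scan.frames[laser]) for laser in LASERS]
        merged = merge(frames, provenance=tuple(steps))
        merged.timestamp = scan.timestamp
        if attach_label and scan.state is not None:
            label(merged, scan.state)
        return merged

    def process_scans(self, scans: Sequence[Scan],
                      attach_label: bool = True) -> list:
        return [self.process_scan(s, attach_label) for s in scans]
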