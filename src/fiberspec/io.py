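"""File formats: per-frame CSV + JSON sidecar, wide merged CSV, features.

Dialects:

* Frame CSV: header ``pixel,intensity``, 460 rows, with a JSON sidecar
  carrying ``excitation_nm, cumulative_on_time_s, timestamp_s`` and an
  optional ``label`` object keyed T/DO/pH/Na/Ca/Glu.
* Wide CSV: columns ``m0..m1379`` plus ``exposure_405_s, exposure_488_s,
  exposure_520_s, timestamp_s`` and optional label columns
  ``label_T, label_DO, label_pH, label_Na, label_Ca, label_Glu``.

Intensities are written as decimal text with 12 significant digits, enough
for a lossless round trip at the pipeline's tolerances.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .channels import (
    BIOMARKERS,
    LABEL_CODES,
    LASERS,
    MERGED_LENGTH,
    SEGMENT_LENGTH,
    BiomarkerState,
)
from .errors import FormatError
from .features import FEATURE_KINDS, FeatureVector
from .preprocess import MergedSpectrum
from .sim import SpectralFrame

_FMT = "%.12g"

_CODE_TO_NAME = {v: k for k, v in LABEL_CODES.items()}


def _label_to_codes(state: BiomarkerState) -> Dict[str, float]:
    return {LABEL_CODES[b]: float(getattr(state, b)) for b in BIOMARKERS}


def _label_from_codes(data: Dict[str, float]) -> BiomarkerState:
    return BiomarkerState(**{_CODE_TO_NAME[c]: float(v)
                             for c, v in data.items()})


def write_frame(path, frame: SpectralFrame,
                label: Optional[BiomarkerState] = None) -> None:
    """Write one frame as ``pixel,intensity`` CSV plus a ``.json`` sidecar."""
    path = Path(path)
    lines = ["pixel,intensity"]
    lines += [f"{i},{_FMT % v}" for i, v in enumerate(frame.intensities)]
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "excitation_nm": frame.excitation_nm,
        "cumulative_on_time_s": frame.cumulative_on_time,
        "timestamp_s": frame.timestamp,
    }
    if label is not None:
        sidecar["label"] = _label_to_codes(label)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def read_frame(path) -> SpectralFrame:
    """Read a frame CSV (+ sidecar); validates length and header."""
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if not lines or lines[0].strip() != "pixel,intensity":
        raise FormatError(f"{path}: expected header 'pixel,intensity'")
    if len(lines) - 1 != SEGMENT_LENGTH:
        raise FormatError(
            f"{path}: frame must have {SEGMENT_LENGTH} rows, "
            f"got {len(lines) - 1}")
    intensities = np.empty(SEGMENT_LENGTH)
    for row, line in enumerate(lines[1:]):
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}: malformed row {row + 1}: {line!r}")
        try:
            pixel, value = int(parts[0]), float(parts[1])
        except ValueError as exc:
            raise FormatError(
                f"{path}: malformed row {row + 1}: {line!r}") from exc
        if pixel != row:
            raise FormatError(f"{path}: out-of-order pixel at row {row + 1}")
        intensities[row] = value
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() \
        else {}
    return SpectralFrame(
        excitation_nm=int(meta.get("excitation_nm", LASERS[0])),
        intensities=intensities,
        cumulative_on_time=float(meta.get("cumulative_on_time_s", 0.0)),
        timestamp=float(meta.get("timestamp_s", 0.0)))


def merged_to_row(merged: MergedSpectrum) -> Dict[str, float]:
    row = {f"m{i}": float(v) for i, v in enumerate(merged.intensities)}
    for laser in LASERS:
        row[f"exposure_{laser}_s"] = merged.exposure_map.get(laser, 0.0)
    row["timestamp_s"] = merged.timestamp
    if merged.label is not None:
        for code, v in _label_to_codes(merged.label).items():
            row[f"label_{code}"] = v
    return row


def write_merged(path, spectra: Sequence[MergedSpectrum]) -> None:
    """Write merged spectra as the combined wide CSV."""
    df = pd.DataFrame([merged_to_row(m) for m in spectra])
    df.to_csv(path, index=False, float_format=_FMT)


def read_merged(path) -> List[MergedSpectrum]:
    """Read the wide CSV back into merged spectra (labels optional)."""
    df = pd.read_csv(path)
    vector_cols = [f"m{i}" for i in range(MERGED_LENGTH)]
    missing = [c for c in vector_cols if c not in df.columns]
    if missing:
        present = sum(c in df.columns for c in vector_cols)
        raise FormatError(
            f"{path}: wide rows must carry m0..m{MERGED_LENGTH - 1} "
            f"({present} intensity columns found)")
    extra = [c for c in df.columns if c.startswith("m") and c[1:].isdigit()
             and int(c[1:]) >= MERGED_LENGTH]
    if extra:
        raise FormatError(f"{path}: unexpected intensity columns {extra[:3]}")
    label_cols = {c: _CODE_TO_NAME.get(c[len("label_"):])
                  for c in df.columns if c.startswith("label_")}
    out = []
    for idx, row in df.iterrows():
        exposure = {laser: float(row.get(f"exposure_{laser}_s", 0.0))
                    for laser in LASERS}
        label = None
        if label_cols and not any(pd.isna(row[c]) for c in label_cols):
            label = BiomarkerState(**{
                name: float(row[c]) for c, name in label_cols.items()})
        out.append(MergedSpectrum(
            intensities=row[vector_cols].to_numpy(dtype=float),
            exposure_map=exposure,
            timestamp=float(row.get("timestamp_s", 0.0)),
            label=label))
    return out


def features_to_table(vectors: Sequence[FeatureVector],
                      exposure_unit_s: float = 60.0) -> pd.DataFrame:
    """One row per scan: ``{channel}_{kind}`` columns, per-laser exposure
    seconds, label columns when present."""
    from .channels import CHANNEL_LASER
    rows = []
    for fv in vectors:
        row = {}
        for name, pf in fv.peaks.items():
            for kind in FEATURE_KINDS:
                row[f"{name}_{kind}"] = float(getattr(pf, kind))
        for laser in LASERS:
            members = [n for n, l in CHANNEL_LASER.items() if l == laser]
            exp_u = fv.exposures.get(members[0], 0.0) if members else 0.0
            row[f"exposure_{laser}_s"] = exp_u * exposure_unit_s
        row["corrected"] = fv.corrected
        row["timestamp_s"] = fv.timestamp
        if fv.label is not None:
            for code, v in _label_to_codes(fv.label).items():
                row[f"label_{code}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_features(path, vectors: Sequence[FeatureVector]) -> None:
    features_to_table(vectors).to_csv(path, index=False, float_format=_FMT)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: empty feature table")
    return df
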