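"""Streaming readout: scan -> preprocess -> features -> correct -> predict.

Replicates the measurement loop of the readout software: each scan's three
frames run through the fixed pipeline, the six predicted concentrations are
pushed into per-biomarker circular buffers (capacity 100), and both the
instantaneous and the 34-point windowed-average series are emitted.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibrate import CalibrationModel
from .channels import BIOMARKERS, BiomarkerState, SensorChannel, \
    default_channels
from .errors import InputError, ParameterError
from .features import extract_features, photobleach_correct
from .preprocess import PreprocessPipeline
from .regress import RegressionBundle, predict, score
from .sim import Scan, ScenarioStage

BUFFER_CAPACITY = 100
WINDOW_POINTS = 34


class ReadoutBuffer:
    """Circular per-biomarker buffer with a windowed-average readout.

    Holds at most ``capacity`` (timestamp, value) pairs per biomarker,
    evicting oldest first; the displayed average uses the
    min(window_points, length) most recent entries.
    """

    def __init__(self, capacity: int = BUFFER_CAPACITY,
                 window_points: int = WINDOW_POINTS):
        if capacity < 1 or window_points < 1:
            raise ParameterError("capacity and window_points must be >= 1")
        self.capacity = capacity
        self.window_points = window_points
        self._buffers: Dict[str, deque] = {
            b: deque(maxlen=capacity) for b in BIOMARKERS}

    def push(self, timestamp: float, state: BiomarkerState) -> None:
        for b in BIOMARKERS:
            self._buffers[b].append((timestamp, float(getattr(state, b))))

    def __len__(self) -> int:
        return len(self._buffers[BIOMARKERS[0]])

    def series(self, biomarker: str) -> List[Tuple[float, float]]:
        return list(self._buffers[biomarker])

    def windowed_average(self) -> Dict[str, float]:
        if len(self) == 0:
            raise InputError("empty readout buffer has no average")
        out = {}
        for b in BIOMARKERS:
            recent = list(self._buffers[b])[-self.window_points:]
            out[b] = float(np.mean([v for _, v in recent]))
        return out


def windowed_average(buffer: ReadoutBuffer) -> Dict[str, float]:
    """Mean of the most recent min(34, n) entries per biomarker."""
    return buffer.windowed_average()


@dataclass
class MonitorResult:
    """Instantaneous + averaged readout series with stage annotations."""

    readout: pd.DataFrame
    buffer: ReadoutBuffer


def run_monitor(source: Iterable[Scan], model: RegressionBundle,
                calibration: CalibrationModel,
                scans: Optional[int] = None,
                pipeline: Optional[PreprocessPipeline] = None,
                channels: Optional[Dict[str, SensorChannel]] = None,
                search_radius: int = 15,
                buffer: Optional[ReadoutBuffer] = None) -> MonitorResult:
    """Run the fixed pipeline over a scan stream and buffer predictions."""
    pipeline = pipeline or PreprocessPipeline()
    channels = channels or default_channels()
    buffer = buffer or ReadoutBuffer()
    taus = calibration.taus()
    rows = []
    for k, scan in enumerate(source):
        if scans is not None and k >= scans:
            break
        merged = pipeline.process_scan(scan, attach_label=False)
        fv = extract_features(merged, channels, search_radius=search_radius)
        fv = photobleach_correct(fv, taus)
        state = predict(model, fv).single()
        buffer.push(scan.timestamp, state)
        avg = buffer.windowed_average()
        row = {"timestamp": scan.timestamp, "stage": scan.stage}
        for b in BIOMARKERS:
            row[b] = float(getattr(state, b))
            row[f"{b}_avg"] = avg[b]
            if scan.state is not None:
                row[f"{b}_true"] = float(getattr(scan.state, b))
        rows.append(row)
    return MonitorResult(readout=pd.DataFrame(rows), buffer=buffer)


def track_scenario(result: MonitorResult | pd.DataFrame,
                   stages: Optional[Sequence[ScenarioStage]] = None
                   ) -> Dict[str, pd.DataFrame]:
    """Per-stage and overall prediction errors against the true trajectory.

    Also reports detection latency per stage: the time from stage onset
    until every averaged biomarker readout has crossed halfway from its
    value at onset toward the stage target (reported at scan granularity).
    """
    readout = result.readout if isinstance(result, MonitorResult) else result
    if readout.empty:
        raise InputError("empty readout series")
    truth_cols = [f"{b}_true" for b in BIOMARKERS]
    if any(c not in readout.columns for c in truth_cols):
        raise InputError("scenario labels unavailable in readout")
    out: Dict[str, pd.DataFrame] = {}
    pred = readout[list(BIOMARKERS)]
    truth = readout[truth_cols].rename(
        columns=dict(zip(truth_cols, BIOMARKERS)))
    out["overall"] = score(pred, truth)
    if "stage" in readout.columns and readout["stage"].notna().any():
        for stage_name, block in readout.groupby("stage", sort=False):
            p = block[list(BIOMARKERS)]
            t = block[truth_cols].rename(
                columns=dict(zip(truth_cols, BIOMARKERS)))
            out[str(stage_name)] = score(p, t)
    if stages is not None:
        out["latency"] = _stage_latencies(readout, stages)
    return out


def _stage_latencies(readout: pd.DataFrame,
                     stages: Sequence[ScenarioStage]) -> pd.DataFrame:
    rows = {}
    for stage in stages:
        block = readout[readout["stage"] == stage.name]
        if block.empty:
            continue
        onset = block["timestamp"].iloc[0]
        latencies = {}
        for b in BIOMARKERS:
            target = float(getattr(stage.target, b))
            series = block[f"{b}_avg"].to_numpy(float)
            start = series[0]
            halfway = start + 0.5 * (target - start)
            if abs(target - start) < 1e-9:
                latencies[b] = 0.0
                continue
            crossed = np.where((series - halfway) * np.sign(target - start)
                               >= 0)[0]
            latencies[b] = (float(block["timestamp"].iloc[crossed[0]] - onset)
                            if crossed.size else float("nan"))
        rows[stage.name] = latencies
    return pd.DataFrame(rows).T


def recovery_rate(baseline_readout: float, spiked_readout: float,
                  spike_amount: float) -> float:
    """Spike-recovery accuracy: 100 x (measured increment / spike), percent."""
    if spike_amount <= 0:
        raise ParameterError("spike_amount must be positive")
    return 100.0 * (spiked_readout - baseline_readout) / spike_amount
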