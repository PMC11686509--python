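"""End-to-end convenience workflows shared by the CLI, tests and scripts.

These functions compose the module surfaces in the fixed pipeline order:
simulate -> denoise -> baseline-correct -> (standardize) -> merge -> label
-> extract -> photobleach-correct -> select -> split -> tune/train -> score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .channels import (
    BIOMARKERS,
    STATE_RANGES,
    BiomarkerState,
    SensorChannel,
    default_channels,
)
from .features import (
    FeatureVector,
    extract_features,
    feature_frame,
    pearson_select,
    photobleach_correct,
)
from .preprocess import PreprocessPipeline
from .regress import (
    FeatureBasis,
    RegressionBundle,
    predict,
    score,
    split_train_test,
    tune_and_train,
)
from .sim import NoiseConfig, Scan, generate_calibration_set

#: Default factorial calibration grids: 5 levels over each channel's
#: characterized range (DO swept from 1 mg/L as in its characterization).
DEFAULT_GRIDS: Dict[str, Sequence[float]] = {
    "temperature": tuple(np.linspace(33.0, 42.0, 5)),
    "dissolved_oxygen": tuple(np.linspace(1.0, 8.0, 5)),
    "pH": tuple(np.linspace(6.0, 8.0, 5)),
    "sodium": tuple(np.linspace(0.0, 200.0, 5)),
    "calcium": tuple(np.linspace(0.0, 2.0, 5)),
    "glucose": tuple(np.linspace(0.0, 6.0, 5)),
}


@dataclass
class TrainedPipeline:
    """Everything produced by one training run."""

    bundle: RegressionBundle
    selection_mask: pd.Series
    correlation_table: pd.DataFrame
    test_scores: pd.DataFrame
    features: pd.DataFrame
    labels: pd.DataFrame


def scans_to_features(scans: Sequence[Scan],
                      channels: Optional[Dict[str, SensorChannel]] = None,
                      pipeline: Optional[PreprocessPipeline] = None,
                      search_radius: int = 15,
                      correct: bool = True) -> List[FeatureVector]:
    """Preprocess scans and extract (optionally corrected) features."""
    channels = channels or default_channels()
    pipeline = pipeline or PreprocessPipeline()
    taus = {name: ch.tau for name, ch in channels.items()}
    out = []
    for scan in scans:
        merged = pipeline.process_scan(scan)
        fv = extract_features(merged, channels, search_radius=search_radius)
        if correct:
            fv = photobleach_correct(fv, taus)
        out.append(fv)
    return out


def train_from_scans(scans: Sequence[Scan],
                     family: str = "bayesian",
                     channels: Optional[Dict[str, SensorChannel]] = None,
                     pipeline: Optional[PreprocessPipeline] = None,
                     threshold: float = 0.5,
                     fraction: float = 0.75,
                     folds: int = 10,
                     seed: int = 42,
                     grid: Optional[Sequence[float]] = None,
                     basis: Optional[FeatureBasis] = None) -> TrainedPipeline:
    """The full training protocol: 75/25 split, k-fold CV, held-out scoring."""
    vectors = scans_to_features(scans, channels=channels, pipeline=pipeline)
    X, Y = feature_frame(vectors, channels=channels)
    if Y is None:
        raise ValueError("training scans must be labeled")
    mask, table = pearson_select(X, Y, threshold=threshold)
    # exposure columns are correction metadata, passed through alongside the
    # correlation-selected features (the tail-bleach mismatch of overlapped
    # peaks depends on exposure even after per-channel correction)
    passthrough = mask.copy()
    passthrough[[c for c in X.columns if c.startswith("exposure_")]] = True
    selected = X.loc[:, passthrough]
    data = list(zip(selected.to_numpy(), Y.to_numpy()))
    train, test = split_train_test(data, fraction=fraction, seed=seed)
    train_X = pd.DataFrame([r[0] for r in train], columns=selected.columns)
    train_Y = pd.DataFrame([r[1] for r in train], columns=Y.columns)
    test_X = pd.DataFrame([r[0] for r in test], columns=selected.columns)
    test_Y = pd.DataFrame([r[1] for r in test], columns=Y.columns)
    bundle = tune_and_train(train_X, train_Y, family=family, grid=grid,
                            folds=folds, seed=seed, basis=basis)
    result = predict(bundle, test_X)
    test_scores = score(result.values, test_Y)
    bundle.test_scores = {
        b: {k: float(v) for k, v in test_scores.loc[b].items()}
        for b in test_scores.index}
    return TrainedPipeline(bundle=bundle, selection_mask=mask,
                           correlation_table=table, test_scores=test_scores,
                           features=X, labels=Y)


def characterization_sweep(channel, values,
                           noise: Optional[NoiseConfig] = None,
                           exposure_s: float = 0.0,
                           pipeline: Optional[PreprocessPipeline] = None
                           ) -> np.ndarray:
    """Single-sensor characterization: peak heights along an analyte sweep.

    Mirrors the bench protocol for characterizing one sensor at a time:
    emit that channel's frame alone at each concentration (all other
    biomarkers at the channel-reference state), run denoise + baseline
    correction, and extract the peak height at the nominal index.
    """
    from .features import extract_channel
    from .sim import emit_spectrum, reference_state

    noise = noise if noise is not None else NoiseConfig.noiseless()
    pipeline = pipeline or PreprocessPipeline()
    base = reference_state()
    heights = []
    for value in values:
        state = base.replace(**{channel.name: float(value)})
        frame = emit_spectrum([channel], state, exposure_s, noise)
        processed = pipeline.process_frame(frame)
        pf = extract_channel(processed.intensities, channel.segment_pixel)
        heights.append(pf.height)
    return np.asarray(heights)


def default_training_scans(n_samples: int = 2000, seed: int = 42,
                           noise: Optional[NoiseConfig] = None,
                           channels: Optional[Dict[str, SensorChannel]] = None
                           ) -> List[Scan]:
    """The default-noise factorial calibration dataset (5^6 subsampled)."""
    return generate_calibration_set(
        grids=dict(DEFAULT_GRIDS), replicates=1,
        noise=noise if noise is not None else NoiseConfig(seed=seed),
        seed=seed, channels=channels, n_samples=n_samples)
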