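"""Shared fixtures: channels, pipelines, and two session-scoped trained
pipelines (noiseless and default-noise) reused across accuracy tests."""

import warnings

import numpy as np
import pytest

from fiberspec.channels import default_channels
from fiberspec.preprocess import PreprocessPipeline
from fiberspec.sim import NoiseConfig, reference_state
from fiberspec.workflow import default_training_scans, train_from_scans

#: Problem sizes for the trained-pipeline fixtures.  Subsampling keeps the
#: suite's runtime modest while leaving the training set larger than the
#: expanded basis.
NOISY_SAMPLES = 2000
NOISELESS_SAMPLES = 1400


@pytest.fixture(scope="session")
def channels():
    return default_channels()


@pytest.fixture(scope="session")
def ref_state(channels):
    return reference_state(channels)


@pytest.fixture()
def noiseless():
    return NoiseConfig.noiseless()


@pytest.fixture()
def pipeline():
    return PreprocessPipeline()


@pytest.fixture(scope="session")
def default_noise_scans():
    """The default-noise factorial calibration dataset (seed 42)."""
    return default_training_scans(n_samples=NOISY_SAMPLES, seed=42)


@pytest.fixture(scope="session")
def trained_default(default_noise_scans):
    """Bayesian-family pipeline trained per the 75/25 + 10-fold protocol."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_from_scans(default_noise_scans, family="bayesian")


@pytest.fixture(scope="session")
def trained_noiseless():
    """Ridge pipeline trained on a dense noiseless factorial sweep.

    Nine levels per biomarker (a deployment-grade calibration: the
    saturating responses need dense levels to interpolate well off-grid),
    subsampled to a set larger than the expanded basis.
    """
    from fiberspec.sim import generate_calibration_set

    grids = {
        "temperature": list(np.linspace(33.0, 42.0, 9)),
        "dissolved_oxygen": list(np.linspace(1.0, 8.0, 9)),
        "pH": list(np.linspace(6.0, 8.0, 9)),
        "sodium": list(np.linspace(0.0, 200.0, 9)),
        "calcium": list(np.linspace(0.0, 2.0, 9)),
        "glucose": list(np.linspace(0.0, 6.0, 9)),
    }
    scans = generate_calibration_set(grids, noise=NoiseConfig.noiseless(),
                                     seed=7, n_samples=NOISELESS_SAMPLES)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_from_scans(scans, family="ridge", grid=[1e-4, 1e-2],
                                folds=5)
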