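# fiberspec

Simulation and readout pipeline for a multiplexed fiber-optic fluorescence
sensing system that monitors six cerebrospinal-fluid (CSF) biomarkers —
temperature, dissolved oxygen (DO), pH, Na⁺, Ca²⁺ and glucose — through one
fiber bundle excited by three pulsed lasers (405, 488, 520 nm).

The package is aimed at people building or analyzing optical multianalyte
monitors: it provides (a) a *digital twin* that generates physically
structured synthetic spectra, and (b) the *inverse pipeline* that turns raw
spectra back into concentrations.

## The model

Each sensing film responds with a dimensionless emission-intensity ratio
R(c) = I/I₀, normalized to 1 at its reference condition:

* **Quenched channels** (temperature, DO) follow a Stern–Volmer law,
  I₀/I = 1 + K·c, with K = 0.04 /°C (reference 33 °C) and
  K = 0.38 L·mg⁻¹ (reference 0 mg/L).
* **Na⁺** is linear: I/I₀ = 1 + 0.0064·[Na⁺] (0.064 per 10 mmol/L).
* **pH, glucose, Ca²⁺** follow four-parameter logistic (4PL) binding
  curves R(c) = A + (B−A)/(1+e^(−k(c−c₀))), constructed so that the
  characterized constraints hold exactly: midpoint slope 2.624 /pH with a
  5× rise from pH 6→8 (c₀ = 7.0); a 4× rise from 1→5 mmol/L glucose;
  a 0.41 /mmol·L⁻¹ linear slope over the physiological Ca²⁺ window
  (c₀ = K_d = 0.5 mmol/L).

A spectral frame is the superposition of Lorentzian peaks (one per channel
on that laser) at fixed pixels {pH 34, glucose 28, DO 341 | Na⁺ 725,
temperature 884 | Ca²⁺ 1262} of the merged 1380-point vector, scaled by
R(c), by exponential photobleaching e^(−t/τ) in the accumulated exposure t
(τ = 51.13, 48.8, 37.0, 22.0, 38.0, 133.7 for T/DO/pH/Na/Ca/glucose), and
by a weak temperature quench, over baseline drift and Gaussian noise.

The inverse pipeline mirrors the readout software: Savitzky–Golay
smoothing → asymmetric penalized least-squares baseline removal →
per-laser standardization → merging → peak features (height, width, area,
position, prominence) → photobleach compensation (×e^(t/τ)) → Pearson
feature selection → multitask regression (linear / ridge / lasso /
Bayesian families on a chemometric linearization basis) → streaming
readout with 100-deep circular buffers and a 34-point display average.

## Worked example

```python
import numpy as np
from fiberspec import default_channels, fit_linear_ratio
from fiberspec.workflow import (characterization_sweep,
                                default_training_scans, train_from_scans)

channels = default_channels()

# 1. single-sensor characterization: recover the DO Stern-Volmer slope
#    through the full spectral round trip (noiseless sweep 0..8 mg/L)
do = np.arange(0.0, 8.5, 1.0)
heights = characterization_sweep(channels["dissolved_oxygen"], do)
slope, intercept, r2 = fit_linear_ratio(do, heights[0] / heights)
print(f"Stern-Volmer slope: {slope:.4f} I0/I per mg/L (R2={r2:.4f})")

# 2. multiplexed calibration: train the Bayesian multitask model on a
#    default-noise factorial sweep and report held-out accuracy
scans = default_training_scans(n_samples=800, seed=42)
trained = train_from_scans(scans, family="bayesian")
print(trained.test_scores.round(4))
```

Output:

```
Stern-Volmer slope: 0.3800 I0/I per mg/L (R2=1.0000)
                     mse     mae      r2
temperature       0.0129  0.0906  0.9988
dissolved_oxygen  0.0258  0.1202  0.9954
pH                0.0032  0.0484  0.9932
sodium            0.2066  0.3575  1.0000
calcium           0.0090  0.0743  0.9822
glucose           0.0687  0.2177  0.9838
```

The first line shows the configured DO sensitivity (0.38 increase in I₀/I
per mg/L) surviving emission, smoothing, baseline correction and feature
extraction. The table gives per-biomarker held-out mean squared error,
mean absolute error and R² of the Bayesian pipeline under the default
noise model — every biomarker is recovered with R² ≥ 0.93 despite the
heavily overlapped 405 nm peaks, varying exposure times and the
temperature quench, which is the point of the regression layer.

A CLI wraps the same workflows:

```bash
fiberspec simulate --scans 200 --seed 1 --out runs/demo
fiberspec train --data runs/demo/merged.csv --family bayesian --out model.json
fiberspec evaluate --model model.json --data runs/demo/merged.csv --report report.json
fiberspec monitor --model model.json --calib cal.json --scenario hypoxia --out series.csv
```

## Layout

| module | contents |
|---|---|
| `fiberspec.channels` | biomarker state, response curves, channel geometry |
| `fiberspec.sim` | frames, pulse schedule, calibration sets, scenarios |
| `fiberspec.preprocess` | smoothing, AsLS baseline, standardize, merge |
| `fiberspec.features` | peak features, photobleach correction, τ fit, selection |
| `fiberspec.calibrate` | curve fitting, two-standard session correction |
| `fiberspec.regress` | basis expansion, four model families, CV, scoring |
| `fiberspec.monitor` | streaming readout, circular buffers, scenario metrics |
| `fiberspec.io` / `.config` / `.cli` | file dialects, strict config, CLI |

See `docs/methods.md` for the modeling conventions, parameter defaults and
known limitations.
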