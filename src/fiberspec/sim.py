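"""Forward simulator: the digital twin of the multiplexed fiber readout.

Generates physically structured synthetic spectra: each channel contributes
a Lorentzian emission peak whose amplitude follows its calibration response,
decays exponentially with accumulated excitation (photobleaching), and is
weakly quenched by temperature; baseline drift and additive Gaussian noise
are superposed per :class:`NoiseConfig`.  The three lasers fire sequentially
in 5 s-on / 5 s-off pulse cycles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .channels import (
    BIOMARKERS,
    DEFAULT_EXPOSURE_UNIT_S,
    HEALTHY_STATE,
    LASERS,
    SEGMENT_LENGTH,
    BiomarkerState,
    SensorChannel,
    default_channels,
    evaluate_response,
)
from .errors import ConfigError


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise and baseline drift of one acquisition.

    Setting every field to zero yields a noiseless, baseline-free spectrum.
    The baseline is ``amplitude * exp(-decay * pixel)`` plus a low-order
    polynomial, mimicking the slow drift seen in raw fluorescence frames.
    """

    additive_sigma: float = 5.0
    baseline_amplitude: float = 100.0
    baseline_decay: float = 3e-4
    baseline_poly_coeffs: Tuple[float, ...] = (20.0, -0.03, 1e-5)
    seed: int = 0

    def __post_init__(self):
        if self.additive_sigma < 0:
            raise ConfigError("additive_sigma must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        return cls(additive_sigma=0.0, baseline_amplitude=0.0,
                   baseline_decay=0.0, baseline_poly_coeffs=(), seed=0)


@dataclass
class SpectralFrame:
    """One laser's 460-point emission spectrum with exposure metadata."""

    excitation_nm: int
    intensities: np.ndarray
    cumulative_on_time: float  # seconds of accumulated excitation
    timestamp: float = 0.0     # seconds since monitoring start

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (SEGMENT_LENGTH,):
            raise ConfigError(
                f"frame must have {SEGMENT_LENGTH} pixels, "
                f"got {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ConfigError("frame intensities must be finite")

    def copy_with(self, intensities: np.ndarray) -> "SpectralFrame":
        return SpectralFrame(self.excitation_nm, np.asarray(intensities, float),
                             self.cumulative_on_time, self.timestamp)


@dataclass(frozen=True)
class PulseSchedule:
    """Sequential pulse excitation: each laser 5 s on, 5 s off by default."""

    on_s: float = 5.0
    off_s: float = 5.0
    order: Tuple[int, ...] = LASERS

    def __post_init__(self):
        if self.on_s <= 0 or self.off_s <= 0:
            raise ConfigError("pulse durations must be positive")
        if tuple(sorted(self.order)) != tuple(sorted(LASERS)):
            raise ConfigError(f"schedule must cover lasers {LASERS}")

    @property
    def cycle_s(self) -> float:
        return len(self.order) * (self.on_s + self.off_s)


@dataclass
class Scan:
    """One full measurement: three frames (one per laser) plus ground truth."""

    frames: Dict[int, SpectralFrame]
    state: BiomarkerState
    timestamp: float = 0.0
    stage: Optional[str] = None


@dataclass(frozen=True)
class ScenarioStage:
    """A held physiological stage of a monitoring scenario."""

    name: str
    target: BiomarkerState
    duration_s: float
    transition_s: float = 0.0

    def __post_init__(self):
        if self.duration_s < 0 or self.transition_s < 0:
            raise ConfigError("stage durations must be >= 0")


#: Physiological presets for post-TBI complications (others at healthy CSF).
STAGE_PRESETS: Dict[str, BiomarkerState] = {
    "healthy": HEALTHY_STATE,
    "hypoxia": HEALTHY_STATE.replace(temperature=38.0, dissolved_oxygen=3.2),
    "hypermetabolism": HEALTHY_STATE.replace(
        temperature=39.0, dissolved_oxygen=3.8, glucose=1.0),
    "excitotoxicity": HEALTHY_STATE.replace(pH=6.5, sodium=180.0, calcium=3.0),
}


def stage_preset(name: str, duration_s: float,
                 transition_s: float = 0.0) -> ScenarioStage:
    if name not in STAGE_PRESETS:
        raise ConfigError(
            f"unknown stage preset {name!r}; choose from {sorted(STAGE_PRESETS)}"
        )
    return ScenarioStage(name, STAGE_PRESETS[name], duration_s, transition_s)


def lorentzian(pixels: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-amplitude Lorentzian line shape on a pixel grid."""
    gamma = fwhm / 2.0
    return 1.0 / (1.0 + ((pixels - center) / gamma) ** 2)


def baseline_profile(noise: NoiseConfig,
                     n: int = SEGMENT_LENGTH) -> np.ndarray:
    """Deterministic baseline drift component of a frame."""
    pixels = np.arange(n, dtype=float)
    base = noise.baseline_amplitude * np.exp(-noise.baseline_decay * pixels)
    if noise.baseline_poly_coeffs:
        base = base + np.polyval(noise.baseline_poly_coeffs[::-1], pixels)
    return base


def peak_amplitude(channel: SensorChannel, state: BiomarkerState,
                   exposure: float, clip: bool = False,
                   exposure_unit_s: float = DEFAULT_EXPOSURE_UNIT_S) -> float:
    """Peak amplitude = base x response x bleaching x temperature quench.

    ``exposure`` is cumulative on-time in seconds; the bleaching exponent
    uses the abstract exposure unit so tau keeps its characterized scale.
    """
    response = evaluate_response(channel, state, clip=clip)
    bleach = np.exp(-(exposure / exposure_unit_s) / channel.tau)
    quench = np.exp(-channel.cross_temperature_coeff
                    * (state.temperature - 33.0))
    return channel.base_amplitude * response * bleach * quench


def emit_spectrum(channels: Sequence[SensorChannel], state: BiomarkerState,
                  exposure: float, noise: NoiseConfig,
                  rng: Optional[np.random.Generator] = None,
                  timestamp: float = 0.0, clip: bool = False,
                  exposure_unit_s: float = DEFAULT_EXPOSURE_UNIT_S
                  ) -> SpectralFrame:
    """Superpose all channels of one laser into a single frame."""
    channels = list(channels)
    if not channels:
        raise ConfigError("emit_spectrum needs at least one channel")
    lasers = {ch.excitation_nm for ch in channels}
    if len(lasers) != 1:
        raise ConfigError(f"channels mix lasers {sorted(lasers)}")
    pixels = np.arange(SEGMENT_LENGTH, dtype=float)
    spectrum = baseline_profile(noise)
    for ch in channels:
        amp = peak_amplitude(ch, state, exposure, clip=clip,
                             exposure_unit_s=exposure_unit_s)
        spectrum = spectrum + amp * lorentzian(pixels, ch.segment_pixel,
                                               ch.peak_fwhm)
    if noise.additive_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        spectrum = spectrum + rng.normal(0.0, noise.additive_sigma,
                                         SEGMENT_LENGTH)
    np.maximum(spectrum, 0.0, out=spectrum)
    return SpectralFrame(lasers.pop(), spectrum, exposure, timestamp)


class Simulator:
    """Stateful digital twin: tracks per-laser exposure and the clock.

    Each :meth:`run_scan` fires the three lasers sequentially per the pulse
    schedule, increments every laser's cumulative on-time by the on
    duration, and advances the clock by a full cycle.
    """

    def __init__(self, channels: Optional[Dict[str, SensorChannel]] = None,
                 schedule: Optional[PulseSchedule] = None,
                 noise: Optional[NoiseConfig] = None,
                 seed: Optional[int] = None,
                 exposure_unit_s: float = DEFAULT_EXPOSURE_UNIT_S,
                 clip: bool = False):
        self.channels = dict(channels) if channels else default_channels()
        self.schedule = schedule or PulseSchedule()
        self.noise = noise if noise is not None else NoiseConfig()
        self.exposure_unit_s = exposure_unit_s
        self.clip = clip
        self.rng = np.random.default_rng(
            self.noise.seed if seed is None else seed)
        self.exposure: Dict[int, float] = {laser: 0.0 for laser in LASERS}
        self.clock: float = 0.0

    def channels_for(self, laser: int) -> List[SensorChannel]:
        return [ch for ch in self.channels.values()
                if ch.excitation_nm == laser]

    def reset_exposure(self) -> None:
        """Start a fresh acquisition session (new/recovered films)."""
        self.exposure = {laser: 0.0 for laser in LASERS}

    def run_scan(self, state: BiomarkerState,
                 stage: Optional[str] = None) -> Scan:
        frames: Dict[int, SpectralFrame] = {}
        t = self.clock
        for laser in self.schedule.order:
            self.exposure[laser] += self.schedule.on_s
            frames[laser] = emit_spectrum(
                self.channels_for(laser), state, self.exposure[laser],
                self.noise, rng=self.rng, timestamp=t, clip=self.clip,
                exposure_unit_s=self.exposure_unit_s)
            t += self.schedule.on_s + self.schedule.off_s
        self.clock += self.schedule.cycle_s
        return Scan(frames, state, timestamp=frames[LASERS[0]].timestamp,
                    stage=stage)


def generate_calibration_set(
        grids: Dict[str, Sequence[float]],
        replicates: int = 1,
        noise: Optional[NoiseConfig] = None,
        seed: int = 0,
        channels: Optional[Dict[str, SensorChannel]] = None,
        n_samples: Optional[int] = None,
        session_scans: int = 120,
        schedule: Optional[PulseSchedule] = None,
        base_state: Optional[BiomarkerState] = None,
        exposure_unit_s: float = DEFAULT_EXPOSURE_UNIT_S) -> List[Scan]:
    """Labeled factorial sweep of merged-spectrum scans.

    The grid's full factorial product (times ``replicates``) is enumerated;
    ``n_samples`` optionally subsamples it without replacement.  Exposure
    accumulates across successive scans and resets every ``session_scans``
    scans, emulating separate acquisition sessions, so photobleaching is
    present (and varied) in the features.  Deterministic given ``seed``.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ConfigError("calibration grids must be non-empty")
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    unknown = set(grids) - set(BIOMARKERS)
    if unknown:
        raise ConfigError(f"unknown biomarkers in grid: {sorted(unknown)}")
    base = base_state or _reference_state(channels or default_channels())
    names = list(grids)
    combos = list(itertools.product(*(grids[n] for n in names)))
    states = []
    for _ in range(replicates):
        for combo in combos:
            states.append(base.replace(**dict(zip(names, combo))))
    rng = np.random.default_rng(seed)
    if n_samples is not None and n_samples < len(states):
        idx = rng.choice(len(states), size=n_samples, replace=False)
        states = [states[i] for i in sorted(idx)]
    # shuffle so sessions (exposure levels) are not confounded with the grid
    rng.shuffle(states)
    noise = noise if noise is not None else NoiseConfig()
    simulator = Simulator(channels=channels, schedule=schedule, noise=noise,
                          seed=seed, exposure_unit_s=exposure_unit_s)
    scans = []
    for i, state in enumerate(states):
        if session_scans and i > 0 and i % session_scans == 0:
            simulator.reset_exposure()
        scans.append(simulator.run_scan(state.validate()))
    return scans


def _reference_state(channels: Dict[str, SensorChannel]) -> BiomarkerState:
    """State placing every channel at its response reference condition."""
    return BiomarkerState(**{
        name: channels[name].response.reference_condition
        for name in BIOMARKERS
    })


def reference_state(channels: Optional[Dict[str, SensorChannel]] = None
                    ) -> BiomarkerState:
    return _reference_state(channels or default_channels())


def scenario_states(stages: Sequence[ScenarioStage], scan_period_s: float
                    ) -> Iterator[Tuple[float, BiomarkerState, str]]:
    """Piecewise trajectory: linear ramp over each transition, then hold."""
    if not stages:
        raise ConfigError("scenario needs at least one stage")
    t = 0.0
    previous = stages[0].target
    for stage in stages:
        if stage.duration_s <= 0:
            raise ConfigError("stage durations must be positive")
        start = t
        end = t + stage.duration_s
        while t < end - 1e-9:
            if stage.transition_s > 0 and (t - start) < stage.transition_s:
                frac = (t - start) / stage.transition_s
                state = BiomarkerState.from_array(
                    (1 - frac) * previous.as_array()
                    + frac * stage.target.as_array())
            else:
                state = stage.target
            yield t, state, stage.name
            t += scan_period_s
        previous = stage.target


def generate_scenario(stages: Sequence[ScenarioStage],
                      noise: Optional[NoiseConfig] = None,
                      channels: Optional[Dict[str, SensorChannel]] = None,
                      schedule: Optional[PulseSchedule] = None,
                      seed: int = 0,
                      exposure_unit_s: float = DEFAULT_EXPOSURE_UNIT_S
                      ) -> List[Scan]:
    """Time series of scans following the staged biomarker trajectory."""
    simulator = Simulator(channels=channels, schedule=schedule,
                          noise=noise if noise is not None else NoiseConfig(),
                          seed=seed, exposure_unit_s=exposure_unit_s,
                          clip=True)
    scans = []
    for _, state, stage_name in scenario_states(stages,
                                                simulator.schedule.cycle_s):
        scans.append(simulator.run_scan(state.validate(clip=True),
                                        stage=stage_name))
    return scans
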