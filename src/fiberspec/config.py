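"""Strict-schema YAML/JSON configuration for the simulator and pipeline.

Unknown keys are rejected; materialized defaults are echoed back so every
run's provenance (config hash + seed) can be logged alongside artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, Optional, Sequence, Tuple

import yaml

from .errors import ConfigError


def _check_keys(section: str, data: Dict[str, Any], cls) -> None:
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown keys in [{section}]: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")


@dataclass
class SimulatorSection:
    noise_sigma: float = 5.0
    baseline_amplitude: float = 100.0
    baseline_decay: float = 3e-4
    baseline_poly_coeffs: Tuple[float, ...] = (20.0, -0.03, 1e-5)
    seed: int = 0
    n_samples: int = 2000
    levels: int = 5
    session_scans: int = 120
    exposure_unit_s: float = 60.0
    tau_overrides: Dict[str, float] = field(default_factory=dict)
    base_amplitude: float = 1000.0
    peak_fwhm: float = 30.0
    cross_temperature_coeff: Optional[float] = None


@dataclass
class PreprocessSection:
    window: int = 11
    order: int = 3
    lam: float = 1e8
    p: float = 0.001
    niter: int = 10


@dataclass
class FeaturesSection:
    search_radius: int = 15
    threshold: float = 0.5
    height_mode: str = "fixed"


@dataclass
class RegressSection:
    family: str = "bayesian"
    folds: int = 10
    fraction: float = 0.75
    seed: int = 42
    basis_degree: int = 3
    penalty_grid: Optional[Tuple[float, ...]] = None


@dataclass
class MonitorSection:
    scan_period_s: float = 30.0
    scenario: str = "healthy"
    scenario_duration_s: float = 1800.0
    transition_s: float = 0.0


@dataclass
class PipelineConfig:
    simulator: SimulatorSection = field(default_factory=SimulatorSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    features: FeaturesSection = field(default_factory=FeaturesSection)
    regress: RegressSection = field(default_factory=RegressSection)
    monitor: MonitorSection = field(default_factory=MonitorSection)

    _SECTIONS = {
        "simulator": SimulatorSection,
        "preprocess": PreprocessSection,
        "features": FeaturesSection,
        "regress": RegressSection,
        "monitor": MonitorSection,
    }

    @classmethod
    def from_dict(cls, data: Optional[Dict[str, Any]]) -> "PipelineConfig":
        data = data or {}
        unknown = set(data) - set(cls._SECTIONS)
        if unknown:
            raise ConfigError(
                f"unknown config sections: {sorted(unknown)}; "
                f"allowed: {sorted(cls._SECTIONS)}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            section = data.get(name, {}) or {}
            if not isinstance(section, dict):
                raise ConfigError(f"section [{name}] must be a mapping")
            _check_keys(name, section, section_cls)
            for key, value in section.items():
                if isinstance(value, list):
                    section[key] = tuple(value)
            kwargs[name] = section_cls(**section)
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if data is not None and not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> Dict[str, Any]:
        return {name: asdict(getattr(self, name)) for name in self._SECTIONS}

    def config_hash(self) -> str:
        """Stable hash of the materialized config, for provenance logs."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
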