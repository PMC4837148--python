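"""Experiment configuration: defaults, validation, YAML/JSON round-trips."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .adaptation import DEFAULT_LEARNING_RATIO, AdaptationConfig
from .exceptions import ConfigError, ParameterError
from .population import StimulationConfig


@dataclasses.dataclass(frozen=True)
class PopulationParams:
    n_per_side: int = 1000
    rate_mean: float = 26.3
    rate_sd: float = 6.6
    regular_fraction: float = 0.67
    cv_range_regular: tuple = (0.01, 0.1)
    cv_range_irregular: tuple = (0.1, 0.3)

    def __post_init__(self) -> None:
        problems = []
        if self.n_per_side < 1:
            problems.append(f"population.n_per_side must be >= 1, got {self.n_per_side}")
        if self.rate_mean <= 0 or self.rate_sd <= 0:
            problems.append("population.rate_mean and rate_sd must be > 0")
        if not 0.0 <= self.regular_fraction <= 1.0:
            problems.append(f"population.regular_fraction must be in [0, 1], got {self.regular_fraction}")
        if problems:
            raise ParameterError("; ".join(problems))


@dataclasses.dataclass(frozen=True)
class NucleiParams:
    mean_magnitude: float = 1.0
    spread: float = 0.2
    output_gain: float = 10.0
    input_scale: float = 3.5e-4
    rate_scale: float = 26.3

    def __post_init__(self) -> None:
        if self.mean_magnitude <= 0 or self.spread < 0:
            raise ParameterError("nuclei.mean_magnitude must be > 0 and spread >= 0")
        if min(self.output_gain, self.input_scale, self.rate_scale) <= 0:
            raise ParameterError("nuclei.output_gain, input_scale and rate_scale must be > 0")


@dataclasses.dataclass(frozen=True)
class ScanParams:
    residual_means: tuple = tuple(np.linspace(5, 60, 12).round(3))
    baseline_rates: tuple = tuple(np.linspace(50, 400, 12).round(3))
    ratios: tuple = tuple(np.logspace(0, 5, 11).round(6))
    depths: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    depth_baseline_rates: tuple = (100.0, 200.0)
    pam_depths: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    prm_depths: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    contour_pam_depths: tuple = (0.05, 0.1, 0.125, 0.15, 0.2, 0.25)


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce any experiment of the suite."""

    population: PopulationParams = PopulationParams()
    stimulation: StimulationConfig = StimulationConfig()
    nuclei: NucleiParams = NucleiParams()
    adaptation: AdaptationConfig = AdaptationConfig()
    scan: ScanParams = ScanParams()
    mod_depth: float = 0.25
    learning_ratio: float = DEFAULT_LEARNING_RATIO
    seed: int = 0
    n_cycles: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ParameterError(f"mod_depth must be in [0, 1], got {self.mod_depth}")
        if self.learning_ratio <= 0:
            raise ParameterError(f"learning_ratio must be > 0, got {self.learning_ratio}")
        if self.n_cycles < 2:
            raise ParameterError(f"n_cycles must be >= 2, got {self.n_cycles}")

    def adaptation_with_ratio(self) -> AdaptationConfig:
        return self.adaptation.replace(alpha_b=self.learning_ratio * self.adaptation.alpha_s)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list, np.ndarray)):
                return [convert(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return convert(self)


_SECTION_TYPES = {
    "population": PopulationParams,
    "stimulation": StimulationConfig,
    "nuclei": NucleiParams,
    "adaptation": AdaptationConfig,
    "scan": ScanParams,
}


def _build_section(cls, data: dict, section: str, problems: list):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        problems.append(f"unknown key {section}.{key}")
    clean = {}
    for k, v in data.items():
        if k in known:
            clean[k] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**clean)
    except (ParameterError, TypeError) as exc:
        problems.append(str(exc))
        return cls()


def config_from_dict(data: dict) -> ExperimentConfig:
    """Build a validated ExperimentConfig; aggregates every violation."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(["top level must be a mapping"])
    problems: list = []
    kwargs = {}
    top_known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    for key in sorted(set(data) - top_known):
        problems.append(f"unknown key {key}")
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            if not isinstance(data[section], dict):
                problems.append(f"{section} must be a mapping")
            else:
                kwargs[section] = _build_section(cls, data[section], section, problems)
    for scalar in ("mod_depth", "learning_ratio", "seed", "n_cycles"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    try:
        cfg = ExperimentConfig(**kwargs)
    except (ParameterError, TypeError) as exc:
        problems.append(str(exc))
        cfg = None
    if problems:
        raise ConfigError(problems)
    return cfg


def load_config(path) -> ExperimentConfig:
    """Load a YAML or JSON experiment configuration, filling defaults.

    An empty file yields the all-defaults configuration.  Unknown keys and
    invalid values are all reported together in a single ConfigError.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    return config_from_dict(data)


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash of the full configuration for provenance records."""
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
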