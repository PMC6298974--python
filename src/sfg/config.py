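"""Run configuration: defaults, YAML round-trip, validation.

A :class:`RunConfig` bundles every knob of an end-to-end run — stimulus
parameters, task design, observer parameters, analysis options, the master
seed and the output directory.  Absent fields fall back to the published
recipe defaults (50-ms chords, 10-ms ramps, 44.1 kHz, the 129-frequency
pool, 60/40 figure/catch composition, 0.4-s exclusion, 5000 bootstrap
repetitions).  Unknown keys are rejected by name so a typo cannot silently
change a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .session import TaskDesign, ObserverParams
from .stimgen import ParameterError

__all__ = ["StimulusConfig", "AnalysisConfig", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration file failed validation; the message names the key."""


@dataclass(frozen=True)
class StimulusConfig:
    """Stimulus-synthesis parameters (defaults = behavioural recipe)."""

    variant: str = "behavioural"
    n_per_condition: int = 5
    coherence_levels: tuple[int, ...] = (4, 6, 8, 10, 12)
    figure_len_chords: int = 20
    chord_duration: float = 0.05
    ramp_duration: float = 0.01
    sample_rate: float = 44100.0
    f_min: float = 179.0
    f_max: float = 7246.0
    steps_per_octave: int = 24
    float32_wav: bool = False


@dataclass(frozen=True)
class AnalysisConfig:
    """Behavioural-analysis options."""

    output_latency: float = 0.0
    exclude_below: float = 0.4
    n_boot: int = 5000
    ci_level: float = 0.95
    sphericity_alpha: float = 0.05
    correction: str = "lower-bound"
    rt_bin_width: float = 0.04


@dataclass(frozen=True)
class RunConfig:
    """Everything an end-to-end run needs; round-trips losslessly via YAML."""

    seed: int = 0
    n_sessions: int = 2
    out_dir: str = "sfg_run"
    stimuli: StimulusConfig = field(default_factory=StimulusConfig)
    task: TaskDesign = field(default_factory=TaskDesign)
    observer: ObserverParams = field(default_factory=ObserverParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "stimuli": StimulusConfig,
    "task": TaskDesign,
    "observer": ObserverParams,
    "analysis": AnalysisConfig,
}
_TUPLE_KEYS = {"coherence_levels", "onset_range"}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    clean = {
        k: tuple(v) if k in _TUPLE_KEYS and v is not None else v for k, v in data.items()
    }
    try:
        return cls(**clean)
    except (TypeError, ParameterError) as exc:
        raise ConfigError(f"invalid value in '{section}': {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    """Validate a nested dict (e.g. parsed YAML) into a RunConfig."""
    data = dict(data or {})
    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML config file, filling defaults for absent fields."""
    path = Path(path)
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(data or {})


def save_config(config: RunConfig, path) -> None:
    """Write the fully resolved configuration (every field explicit)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
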