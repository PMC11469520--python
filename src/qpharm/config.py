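"""YAML run configuration with strict unknown-key rejection."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .extraction import ExtractionConfig
from .features import FeatureClass
from .predictor import PredictorConfig
from .rl import GraphThresholds, QTrainConfig


def _build(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown keys in section '{section}': {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{section}': {exc}") from exc


@dataclass
class RunConfig:
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    thresholds: GraphThresholds = field(default_factory=GraphThresholds)
    qtrain: QTrainConfig = field(default_factory=QTrainConfig)
    log_level: str = "INFO"
    output_dir: str = "qpharm_out"


_SECTIONS = {
    "predictor": PredictorConfig,
    "extraction": ExtractionConfig,
    "thresholds": GraphThresholds,
    "qtrain": QTrainConfig,
}


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration in {path} must be a mapping")
    known = set(_SECTIONS) | {"log_level", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}; "
                          f"allowed: {sorted(known)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        data = dict(raw.get(name, {}))
        if name == "extraction" and "comp_group_dist" in data:
            data["comp_group_dist"] = {
                FeatureClass[k]: float(v)
                for k, v in data["comp_group_dist"].items()}
        if name == "predictor" and "channels" in data:
            data["channels"] = tuple(data["channels"])
        kwargs[name] = _build(cls, data, name)
    kwargs["log_level"] = str(raw.get("log_level", "INFO"))
    kwargs["output_dir"] = str(raw.get("output_dir", "qpharm_out"))
    return RunConfig(**kwargs)
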