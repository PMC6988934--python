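"""YAML experiment configuration: plant, field, memory and tuning overrides."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .environment import CHANNEL_DAMPING, CHANNEL_SPRING, CURL_K, PlantParams
from .memory import TuningParams
from .protocol import ProtocolConfig

__all__ = ["ExperimentConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class FieldConfig:
    k_magnitude: float = CURL_K
    spring: float = CHANNEL_SPRING
    damping: float = CHANNEL_DAMPING


@dataclass(frozen=True)
class MemoryConfig:
    retention: float = 0.99
    learning_rate: float = 0.1
    forgetting_trials: int = 200
    error_ref_m: float = 0.07


@dataclass(frozen=True)
class ExperimentConfig:
    """Bundle of all tunable parameters of the simulation pipeline."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    plant: PlantParams = field(default_factory=PlantParams)
    field_params: FieldConfig = field(default_factory=FieldConfig)
    memory: MemoryConfig = field(default_factory=MemoryConfig)
    tuning: TuningParams = field(default_factory=TuningParams)


def _tuning_to_dict(t: TuningParams) -> dict:
    return {
        "sigma_duration": dict(t.sigma_duration),
        "sigma_speed": dict(t.sigma_speed),
        "distance_halfwidth": dict(t.distance_halfwidth),
        # nested {trained: {probe: gain}} so YAML needs no tuple keys
        "modality_gain": {
            tr: {pr: g for (t2, pr), g in t.modality_gain.items() if t2 == tr}
            for tr in {k[0] for k in t.modality_gain}
        },
        "reversal_gain": dict(t.reversal_gain),
    }


def _tuning_from_dict(d: dict) -> TuningParams:
    base = TuningParams()
    gains = d.get("modality_gain")
    if gains is not None:
        flat = {(tr, pr): g for tr, sub in gains.items() for pr, g in sub.items()}
    else:
        flat = base.modality_gain
    return TuningParams(
        sigma_duration=d.get("sigma_duration", base.sigma_duration),
        sigma_speed=d.get("sigma_speed", base.sigma_speed),
        distance_halfwidth=d.get("distance_halfwidth", base.distance_halfwidth),
        modality_gain=flat,
        reversal_gain=d.get("reversal_gain", base.reversal_gain),
    )


def save_config(config: ExperimentConfig, path) -> None:
    payload = {
        "protocol": vars(config.protocol).copy(),
        "plant": vars(config.plant).copy(),
        "field": vars(config.field_params).copy(),
        "memory": vars(config.memory).copy(),
        "tuning": _tuning_to_dict(config.tuning),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_config(path) -> ExperimentConfig:
    """Load a YAML config; omitted sections and keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    protocol = ProtocolConfig(**raw.get("protocol", {}))
    plant = PlantParams(**raw.get("plant", {}))
    fieldp = FieldConfig(**raw.get("field", {}))
    memory = MemoryConfig(**raw.get("memory", {}))
    tuning = _tuning_from_dict(raw.get("tuning", {}))
    return ExperimentConfig(
        protocol=protocol,
        plant=plant,
        field_params=fieldp,
        memory=memory,
        tuning=tuning,
    )
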