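import dataclasses

import pytest

from curladapt.kinematics import KinematicCondition
from curladapt.memory import default_memory
from curladapt.environment import PlantParams
from curladapt.protocol import TrialSpec


@pytest.fixture
def train_passive() -> KinematicCondition:
    """Training lead-in: 10 cm, 700 ms, passive, from the 225 deg start."""
    return KinematicCondition(0.10, 0.70, "passive", lead_in_angle_deg=225.0)


@pytest.fixture
def quiet_plant() -> PlantParams:
    return PlantParams(motor_noise_sd=0.0)


@pytest.fixture
def make_spec(train_passive):
    """Factory for a single trial spec toward the 0 deg target."""

    def _make(trial_type="field", field_direction="cw", lead_in=None):
        return TrialSpec(
            day=1,
            phase="exposure",
            block_index=0,
            trial_type=trial_type,
            field_direction=field_direction,
            target_angle=0.0,
            lead_in=lead_in or train_passive,
            condition_index=0 if trial_type == "channel" else None,
        )

    return _make


@pytest.fixture
def memory_with(train_passive):
    """Memory over both contexts at a given compensation weight."""

    def _make(w: float):
        mem = default_memory(train_passive)
        return dataclasses.replace(mem, w_cw=w, w_ccw=w)

    return _make
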