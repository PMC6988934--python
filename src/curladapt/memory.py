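"""Contextual motor memory with kinematically tuned recall.

Two compensation weights (one per opposing curl-field context) are learned
trial-by-trial with a single-rate state-space rule, w <- A*w + B*e.  Recall
of a weight on a probe trial is scaled by a tuning function of the probe
lead-in's kinematics relative to the trained lead-in: Gaussian in duration,
Gaussian in peak speed, saturating in distance (full recall at and beyond
the trained distance, falling off for shorter lead-ins), with multiplicative
gains for cross-modal and reversed-visual probes.

The tuning functional forms are a modelling choice: the experiment
constrains only their qualitative shape (recall falls off with duration and
speed offsets, is flat above the trained distance, is narrower for passive
than for visual lead-ins, and transfers asymmetrically across modalities).
Width and gain defaults are calibrated to the published group results and
should be treated as calibration, not as fitted estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .kinematics import KinematicCondition

__all__ = [
    "TuningParams",
    "MemoryState",
    "recall_weight",
    "predict_compensation",
    "update",
    "default_tuning",
    "default_memory",
]

CONTEXTS = ("cw", "ccw")


@dataclass(frozen=True)
class TuningParams:
    """Widths and gains of the kinematic recall tuning, per lead-in modality.

    sigma_duration : s
        Gaussian width of recall over lead-in duration offsets.
    sigma_speed : m/s
        Gaussian width over peak-speed offsets.
    distance_halfwidth : m
        Half-Gaussian width below the trained distance; recall saturates
        at 1 for probe distances at or above the trained distance.
    modality_gain : dict[(trained, probe) -> gain in [0, 1]]
        Multiplicative transfer gain for cross-modal probes.
    reversal_gain : dict[trained -> gain in [0, 1]]
        Gain for the reversed-visual ("lead-away") probe.
    """

    sigma_duration: dict = field(
        default_factory=lambda: {"passive": 0.45, "visual": 0.70}
    )
    sigma_speed: dict = field(
        default_factory=lambda: {"passive": 0.25, "visual": 0.40}
    )
    distance_halfwidth: dict = field(
        default_factory=lambda: {"passive": 0.05, "visual": 0.08}
    )
    modality_gain: dict = field(
        default_factory=lambda: {
            ("passive", "passive"): 1.0,
            ("visual", "visual"): 1.0,
            ("passive", "visual"): 0.352,
            ("visual", "passive"): 0.130,
        }
    )
    reversal_gain: dict = field(
        default_factory=lambda: {"passive": 0.227, "visual": 0.293}
    )

    def __post_init__(self) -> None:
        for d in (self.sigma_duration, self.sigma_speed, self.distance_halfwidth):
            if any(w <= 0 for w in d.values()):
                raise ValueError("tuning widths must be positive")
        for g in (*self.modality_gain.values(), *self.reversal_gain.values()):
            if not 0.0 <= g <= 1.0:
                raise ValueError("gains must lie in [0, 1]")


def default_tuning() -> TuningParams:
    return TuningParams()


def recall_weight(
    probe: KinematicCondition,
    trained: KinematicCondition,
    tuning: TuningParams,
) -> float:
    """Fraction of a trained memory recalled at a probe lead-in, in [0, 1].

    Product of a duration Gaussian, a peak-speed Gaussian, a saturating
    distance term, and modality/reversal gains.  Equals 1 at the trained
    condition.  Tuning widths are those of the *trained* modality — the
    memory was encoded with that modality's sensory precision.
    """
    if probe.modality == "reversed_visual":
        gain = tuning.reversal_gain[trained.modality]
    else:
        gain = tuning.modality_gain[(trained.modality, probe.modality)]
    sd = tuning.sigma_duration[trained.modality]
    sv = tuning.sigma_speed[trained.modality]
    hw = tuning.distance_halfwidth[trained.modality]

    g_dur = math.exp(-0.5 * ((probe.duration - trained.duration) / sd) ** 2)
    g_spd = math.exp(-0.5 * ((probe.peak_speed - trained.peak_speed) / sv) ** 2)
    if probe.distance >= trained.distance:
        g_dist = 1.0
    else:
        g_dist = math.exp(
            -0.5 * ((probe.distance - trained.distance) / hw) ** 2
        )
    return gain * g_dur * g_spd * g_dist


@dataclass(frozen=True)
class MemoryState:
    """Compensation weights for the two field contexts plus learning params.

    w_cw, w_ccw : unitless compensation fractions (1 = full cancellation).
    retention : A in (0, 1]; learning_rate : B in (0, 1).
    trained : the trained lead-in condition per context.
    """

    w_cw: float = 0.0
    w_ccw: float = 0.0
    retention: float = 0.99
    learning_rate: float = 0.1
    trained: dict = field(default_factory=dict)  # context -> KinematicCondition
    tuning: TuningParams = field(default_factory=TuningParams)

    def __post_init__(self) -> None:
        if not 0.0 < self.retention <= 1.0:
            raise ValueError("retention A must be in (0, 1]")
        if not 0.0 < self.learning_rate < 1.0:
            raise ValueError("learning rate B must be in (0, 1)")

    def weight(self, context: str) -> float:
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        return self.w_cw if context == "cw" else self.w_ccw

    def apply_forgetting(self, n_trials: int = 200) -> "MemoryState":
        """Between-session decay: one application of A**n_trials."""
        f = self.retention**n_trials
        return replace(self, w_cw=self.w_cw * f, w_ccw=self.w_ccw * f)


def default_memory(
    trained_condition: KinematicCondition, tuning: TuningParams | None = None
) -> MemoryState:
    """Naive memory with the same trained lead-in kinematics in both contexts."""
    return MemoryState(
        trained={"cw": trained_condition, "ccw": trained_condition},
        tuning=tuning or TuningParams(),
    )


def predict_compensation(
    memory: MemoryState, probe: KinematicCondition, context: str
) -> float:
    """Recalled compensation fraction for a probe lead-in in one context."""
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if context not in memory.trained:
        raise ValueError(f"context {context!r} has no trained condition")
    return memory.weight(context) * recall_weight(
        probe, memory.trained[context], memory.tuning
    )


def update(
    memory: MemoryState,
    error: float,
    context: str,
    probe: KinematicCondition | None = None,
) -> MemoryState:
    """One trial-by-trial learning step after a field trial.

    ``error`` is the normalized signed lateral error (positive = field
    under-compensated).  The experienced context receives the state-space
    update w <- A*w + B*e, scaled by soft credit equal to the recall weight
    of its trained condition at the experienced probe (1 when the probe is
    the trained lead-in).  The opposing context, cued by the other lead-in
    direction, receives no credit.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    trained = memory.trained.get(context)
    if probe is None or trained is None:
        credit = 1.0
    else:
        credit = recall_weight(probe, trained, memory.tuning)
    w = memory.weight(context)
    A, B = memory.retention, memory.learning_rate
    w_new = w + credit * ((A - 1.0) * w + B * error)
    if context == "cw":
        return replace(memory, w_cw=w_new)
    return replace(memory, w_ccw=w_new)


def memory_trajectory_frame(history: list[tuple[int, MemoryState]]) -> pd.DataFrame:
    """Per-trial weight trajectory as a tidy table."""
    return pd.DataFrame(
        {
            "trial_index": [i for i, _ in history],
            "w_cw": [m.w_cw for _, m in history],
            "w_ccw": [m.w_ccw for _, m in history],
        }
    )
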