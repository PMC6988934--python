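"""Two-day trial schedule: block structure, ordering constraints, counterbalancing.

The experiment trains two opposing velocity-dependent curl fields, each
cued by the direction of a lead-in movement, then probes generalization
with channel trials whose lead-in kinematics are drawn from the 17-condition
grid.  Day 1 runs pre-exposure (null field), a familiarization pass over
all probe lead-ins, more pre-exposure, field-exposure training and six
generalization blocks; day 2 resumes exposure briefly and runs ten more
generalization blocks.  Within a block trials are ordered pseudo-randomly
under the constraints that channel trials are never adjacent and never
first in a block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .kinematics import (
    KinematicCondition,
    TRAINING_DISTANCE_M,
    TRAINING_DURATION_S,
    condition_grid,
)

__all__ = [
    "TrialSpec",
    "Schedule",
    "ProtocolConfig",
    "ScheduleReport",
    "build_schedule",
    "validate_schedule",
    "field_context",
    "ADAPT_DISTANCE_M",
    "ADAPT_DURATION_S",
    "TARGET_ANGLES",
    "LEAD_IN_STARTS",
    "CHANNEL_LEAD_INS",
    "DESIGN_COUNTS",
]

#: Adaptation movement: 18 cm from the central via point to the target.
ADAPT_DISTANCE_M = 0.18
#: Desired adaptation duration: midpoint of the rewarded 450-600 ms band.
ADAPT_DURATION_S = 0.525

TARGET_ANGLES = (0.0, 270.0)
#: Lead-in start locations (deg, CCW from +x about the via point) per target.
LEAD_IN_STARTS = {0.0: (135.0, 225.0), 270.0: (45.0, 135.0)}
#: Channel trials occur only on movements to the 0 deg target.
CHANNEL_LEAD_INS = (135.0, 225.0)

#: Published per-phase totals of the default two-day protocol (validator reference).
DESIGN_COUNTS = {
    "day1": 1546,
    "day2": 1580,
    "total": 3126,
    "field_total": 2248,
    "generalization_channels": 544,
    "familiarization_channels": 102,
    "day1_exposure": 480,
    "day2_exposure": 240,
    "day1_generalization": 804,
    "day2_generalization": 1340,
    "distinct_probes": 34,
    "probe_repetitions": 16,
}


def field_context(
    target_angle: float, lead_in_angle: float, counterbalanced: bool = False
) -> str:
    """Field direction ('cw' or 'ccw') cued by a lead-in start location.

    The lead-in moves from its start location to the via point, so its
    movement direction is ``lead_in_angle + 180``.  A lead-in arriving at
    +45 deg relative to the upcoming adaptation direction cues the CW
    field by default; the counterbalance flag swaps the mapping.
    """
    lead_dir = (lead_in_angle + 180.0) % 360.0
    rel = ((lead_dir - target_angle + 180.0) % 360.0) - 180.0
    cw = rel > 0
    if counterbalanced:
        cw = not cw
    return "cw" if cw else "ccw"


@dataclass(frozen=True)
class TrialSpec:
    """Full description of one two-part trial."""

    day: int
    phase: str  # pre_exposure | familiarization | exposure | generalization
    block_index: int
    trial_type: str  # null | field | channel
    field_direction: str  # cw | ccw | none
    target_angle: float
    lead_in: KinematicCondition
    is_transfer_probe: bool = False
    is_reversed_probe: bool = False
    condition_index: int | None = None  # grid index, channel trials only

    def probe_id(self) -> tuple[int, float] | None:
        """Identity of a generalization probe: (grid index, start angle)."""
        if self.trial_type != "channel" or self.condition_index is None:
            return None
        return (self.condition_index, self.lead_in.lead_in_angle_deg)


@dataclass
class Schedule:
    """Ordered two-day trial list for one participant."""

    trials: list[TrialSpec]
    participant: int
    counterbalanced: bool
    seed: int
    trained_modality: str
    #: 1-based trial counts after which a rest break is taken.
    rest_breaks: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def day(self, day: int) -> list[TrialSpec]:
        return [t for t in self.trials if t.day == day]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.trials):
            rows.append(
                {
                    "trial": i,
                    "day": t.day,
                    "phase": t.phase,
                    "block": t.block_index,
                    "trial_type": t.trial_type,
                    "field_direction": t.field_direction,
                    "target_angle": t.target_angle,
                    "lead_in_angle": t.lead_in.lead_in_angle_deg,
                    "lead_in_distance_m": t.lead_in.distance,
                    "lead_in_duration_s": t.lead_in.duration,
                    "lead_in_modality": t.lead_in.modality,
                    "is_transfer_probe": t.is_transfer_probe,
                    "is_reversed_probe": t.is_reversed_probe,
                    "condition_index": t.condition_index,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "participant": self.participant,
            "counterbalanced": self.counterbalanced,
            "seed": self.seed,
            "trained_modality": self.trained_modality,
            "rest_breaks": self.rest_breaks,
            "trials": [
                {**asdict(t), "lead_in": asdict(t.lead_in)} for t in self.trials
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Schedule":
        with open(path) as fh:
            payload = json.load(fh)
        trials = []
        for row in payload["trials"]:
            lead = KinematicCondition(**row.pop("lead_in"))
            trials.append(TrialSpec(**{**row, "lead_in": lead}))
        return cls(
            trials=trials,
            participant=payload["participant"],
            counterbalanced=payload["counterbalanced"],
            seed=payload["seed"],
            trained_modality=payload["trained_modality"],
            rest_breaks=payload["rest_breaks"],
        )


@dataclass(frozen=True)
class ProtocolConfig:
    """Phase structure of the two-day protocol (defaults = published design)."""

    trained_modality: str = "passive"
    pre_blocks_before: int = 2
    pre_blocks_after: int = 2
    familiarization_reps: int = 3
    exposure_blocks_day1: int = 12
    exposure_blocks_day2: int = 6
    gen_blocks_day1: int = 6
    gen_blocks_day2: int = 10
    main_per_forty_block: int = 36  # null or field trials in a 40-trial block
    channels_per_forty_block: int = 4
    field_per_gen_block: int = 100
    rest_break_min: int = 195
    rest_break_max: int = 205


def _nonadjacent_positions(n_total: int, n_special: int, rng: np.random.Generator):
    """Uniformly sample positions for ``n_special`` trials within a block of
    ``n_total`` such that no position is 0 and no two are adjacent.

    Uses the standard gap bijection: strictly increasing picks q from
    [1, n_total - n_special] map to positions q_i + (i - 1), which is a
    bijection onto the valid position sets, so sampling q uniformly
    without replacement yields a uniform valid placement.
    """
    if n_special == 0:
        return np.empty(0, dtype=int)
    n_slots = n_total - n_special
    if n_slots < n_special:
        raise ValueError("cannot place channel trials without adjacency")
    q = rng.choice(np.arange(1, n_slots + 1), size=n_special, replace=False)
    q.sort()
    return q + np.arange(n_special)


def _interleave(
    main: list[TrialSpec], channels: list[TrialSpec], rng: np.random.Generator
) -> list[TrialSpec]:
    """Shuffle a block so channel trials are never first nor adjacent."""
    n = len(main) + len(channels)
    pos = _nonadjacent_positions(n, len(channels), rng)
    main_order = rng.permutation(len(main))
    chan_order = rng.permutation(len(channels))
    out: list[TrialSpec | None] = [None] * n
    for p, j in zip(pos, chan_order):
        out[p] = channels[j]
    it = iter(main_order)
    for i in range(n):
        if out[i] is None:
            out[i] = main[next(it)]
    return out  # type: ignore[return-value]


def _main_trial_combos() -> list[tuple[float, float]]:
    return [(tgt, ang) for tgt in TARGET_ANGLES for ang in LEAD_IN_STARTS[tgt]]


class _Builder:
    def __init__(self, config: ProtocolConfig, counterbalanced: bool):
        self.cfg = config
        self.cb = counterbalanced
        self.grid = condition_grid(config.trained_modality)
        self.training_condition = self.grid[0]
        self.block_index = 0
        other = "visual" if config.trained_modality == "passive" else "passive"
        self.transfer_modality = other

    def _lead_in(self, cond: KinematicCondition, angle: float) -> KinematicCondition:
        return cond.with_angle(angle)

    def _main_trials(self, day, phase, trial_type, n_each) -> list[TrialSpec]:
        trials = []
        for tgt, ang in _main_trial_combos():
            ctx = field_context(tgt, ang, self.cb)
            for _ in range(n_each):
                trials.append(
                    TrialSpec(
                        day=day,
                        phase=phase,
                        block_index=self.block_index,
                        trial_type=trial_type,
                        field_direction=ctx if trial_type == "field" else "none",
                        target_angle=tgt,
                        lead_in=self._lead_in(self.training_condition, ang),
                    )
                )
        return trials

    def _channel(self, day, phase, cond_index, angle) -> TrialSpec:
        cond = self.grid[cond_index]
        ctx = field_context(0.0, angle, self.cb)
        return TrialSpec(
            day=day,
            phase=phase,
            block_index=self.block_index,
            trial_type="channel",
            field_direction=ctx,
            target_angle=0.0,
            lead_in=self._lead_in(cond, angle),
            is_transfer_probe=(cond.modality == self.transfer_modality),
            is_reversed_probe=(cond.modality == "reversed_visual"),
            condition_index=cond_index,
        )

    def forty_block(self, day, phase, rng) -> list[TrialSpec]:
        """36 null/field trials (9 per type) + 4 channels (training x2, transfer x2)."""
        trial_type = "null" if phase == "pre_exposure" else "field"
        n_each = self.cfg.main_per_forty_block // 4
        main = self._main_trials(day, phase, trial_type, n_each)
        channels = [
            self._channel(day, phase, 0, CHANNEL_LEAD_INS[0]),
            self._channel(day, phase, 0, CHANNEL_LEAD_INS[1]),
            self._channel(day, phase, 15, CHANNEL_LEAD_INS[0]),
            self._channel(day, phase, 15, CHANNEL_LEAD_INS[1]),
        ]
        block = _interleave(main, channels, rng)
        self.block_index += 1
        return block

    def familiarization(self, day, rng) -> list[TrialSpec]:
        trials = []
        for _ in range(self.cfg.familiarization_reps):
            for ci in range(len(self.grid)):
                for ang in CHANNEL_LEAD_INS:
                    trials.append(self._channel(day, "familiarization", ci, ang))
        order = rng.permutation(len(trials))
        block = [trials[i] for i in order]
        self.block_index += 1
        return block

    def gen_block(self, day, rng) -> list[TrialSpec]:
        """100 field trials (25 per type) + one of each of the 34 probes."""
        n_each = self.cfg.field_per_gen_block // 4
        main = self._main_trials(day, "generalization", "field", n_each)
        channels = [
            self._channel(day, "generalization", ci, ang)
            for ci in range(len(self.grid))
            for ang in CHANNEL_LEAD_INS
        ]
        block = _interleave(main, channels, rng)
        self.block_index += 1
        return block


def build_schedule(
    config: ProtocolConfig | None = None,
    participant_index: int = 0,
    seed: int = 0,
) -> Schedule:
    """Construct the full two-day schedule for one participant.

    The same (seed, participant_index) always yields the same schedule.
    Participant parity sets the counterbalance flag, swapping which
    lead-in direction cues the CW field.
    """
    cfg = config or ProtocolConfig()
    counterbalanced = participant_index % 2 == 1
    rng = np.random.default_rng([seed, participant_index])
    b = _Builder(cfg, counterbalanced)

    trials: list[TrialSpec] = []
    # Day 1
    for _ in range(cfg.pre_blocks_before):
        trials += b.forty_block(1, "pre_exposure", rng)
    trials += b.familiarization(1, rng)
    for _ in range(cfg.pre_blocks_after):
        trials += b.forty_block(1, "pre_exposure", rng)
    for _ in range(cfg.exposure_blocks_day1):
        trials += b.forty_block(1, "exposure", rng)
    for _ in range(cfg.gen_blocks_day1):
        trials += b.gen_block(1, rng)
    # Day 2
    for _ in range(cfg.exposure_blocks_day2):
        trials += b.forty_block(2, "exposure", rng)
    for _ in range(cfg.gen_blocks_day2):
        trials += b.gen_block(2, rng)

    rest_breaks: list[int] = []
    cursor = 0
    while True:
        cursor += int(rng.integers(cfg.rest_break_min, cfg.rest_break_max + 1))
        if cursor >= len(trials):
            break
        rest_breaks.append(cursor)

    return Schedule(
        trials=trials,
        participant=participant_index,
        counterbalanced=counterbalanced,
        seed=seed,
        trained_modality=cfg.trained_modality,
        rest_breaks=rest_breaks,
    )


@dataclass
class ScheduleReport:
    """Constraint-check report; ``ok`` is True when no violations remain."""

    violations: list[str]
    counts: dict

    @property
    def ok(self) -> bool:
        return not self.violations


def _iter_blocks(trials: list[TrialSpec]) -> Iterable[list[TrialSpec]]:
    block: list[TrialSpec] = []
    for t in trials:
        if block and t.block_index != block[0].block_index:
            yield block
            block = []
        block.append(t)
    if block:
        yield block


def validate_schedule(
    schedule: Schedule, expected: dict | None = DESIGN_COUNTS
) -> ScheduleReport:
    """Check ordering constraints and per-phase composition of a schedule.

    Reports (never raises) violations of: channel adjacency / first-trial
    constraints (outside the all-channel familiarization phase), channel
    geometry (0 deg target, 135/225 deg lead-ins), null trials outside
    pre-exposure, rest-break spacing, per-generalization-block probe
    composition, and — when ``expected`` is given — the printed per-phase
    totals of the default protocol.
    """
    v: list[str] = []
    trials = schedule.trials

    for block in _iter_blocks(trials):
        if block[0].phase == "familiarization":
            continue
        bi = block[0].block_index
        if block[0].trial_type == "channel":
            v.append(f"block {bi}: channel trial first in block")
        for a, b2 in zip(block, block[1:]):
            if a.trial_type == "channel" and b2.trial_type == "channel":
                v.append(f"block {bi}: adjacent channel trials")
        if block[0].phase == "generalization":
            probes = sorted(
                t.probe_id() for t in block if t.trial_type == "channel"
            )
            want = sorted(
                (ci, ang) for ci in range(17) for ang in CHANNEL_LEAD_INS
            )
            if probes != want:
                v.append(f"block {bi}: generalization probe composition wrong")

    for i, t in enumerate(trials):
        if t.trial_type == "channel":
            if t.target_angle != 0.0:
                v.append(f"trial {i}: channel trial not toward 0 deg target")
            if t.lead_in.lead_in_angle_deg not in CHANNEL_LEAD_INS:
                v.append(f"trial {i}: channel lead-in angle invalid")
        if t.trial_type == "null" and t.phase not in ("pre_exposure",):
            v.append(f"trial {i}: null trial outside pre-exposure")

    marks = [0] + list(schedule.rest_breaks) + [len(trials)]
    for a, b2 in zip(marks, marks[1:-1]):
        if not (195 <= b2 - a <= 205):
            v.append(f"rest break after {b2}: gap {b2 - a} outside 195-205")

    day1 = schedule.day(1)
    day2 = schedule.day(2)
    by = lambda day, **kw: sum(
        1
        for t in day
        if all(getattr(t, k) == val for k, val in kw.items())
    )
    probe_reps: dict = {}
    for t in trials:
        if t.trial_type == "channel" and t.phase == "generalization":
            probe_reps[t.probe_id()] = probe_reps.get(t.probe_id(), 0) + 1
    counts = {
        "day1": len(day1),
        "day2": len(day2),
        "total": len(trials),
        "field_total": by(trials, trial_type="field"),
        "generalization_channels": by(
            trials, trial_type="channel", phase="generalization"
        ),
        "familiarization_channels": by(trials, phase="familiarization"),
        "day1_exposure": by(day1, phase="exposure"),
        "day2_exposure": by(day2, phase="exposure"),
        "day1_generalization": by(day1, phase="generalization"),
        "day2_generalization": by(day2, phase="generalization"),
        "distinct_probes": len(probe_reps),
        "probe_repetitions": (
            min(probe_reps.values()) if probe_reps else 0
        ),
        "trained_probe_outside_generalization": sum(
            1
            for t in trials
            if t.trial_type == "channel"
            and t.condition_index == 0
            and t.phase in ("pre_exposure", "exposure")
        ),
    }
    if probe_reps and min(probe_reps.values()) != max(probe_reps.values()):
        v.append("unequal generalization probe repetitions")
    if expected:
        for key, want in expected.items():
            if key in counts and counts[key] != want:
                v.append(f"count {key}: got {counts[key]}, expected {want}")
    return ScheduleReport(violations=v, counts=counts)
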