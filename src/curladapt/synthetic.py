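"""Synthetic trial logs with known ground truth, bypassing the simulator.

Every analysis operation can be validated by parameter recovery: channel
logs are built with a planted compensation fraction (learning curve x
kinematic recall tuning) expressed as perpendicular force c*k*v(t) plus
Gaussian force noise, and field/null logs carry a smooth perpendicular
path bump with a planted MPE amplitude.  A smooth bump is used rather
than white positional noise because the MPE of a white-noise path is
biased upward by max-statistics; a single lateral excursion matches the
error shape of curl-field reaching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .environment import (
    PHASE_CODES,
    TrialLog,
    signed_k,
)
from .kinematics import KinematicCondition, min_jerk_profile
from .memory import TuningParams, recall_weight
from .protocol import (
    ADAPT_DISTANCE_M,
    ADAPT_DURATION_S,
    ProtocolConfig,
    Schedule,
    TrialSpec,
    build_schedule,
    field_context,
)

__all__ = ["GroundTruth", "SyntheticDataset", "make_channel_log", "make_mpe_log",
           "make_experiment_dataset"]


@dataclass(frozen=True)
class GroundTruth:
    """Planted generative parameters for a synthetic experiment.

    The compensation available in context c after n field-trial exposures
    follows a single exponential,
    c(n) = asymptote + (initial - asymptote) * exp(-n / rate_trials),
    matching the closed form of a single-rate state-space learner.  The
    compensation expressed on a probe trial is c(n) times the kinematic
    recall weight of the probe relative to the trained condition.
    """

    asymptote: float = 0.627
    initial: float = 0.0
    rate_trials: float = 60.0
    tuning: TuningParams = field(default_factory=TuningParams)
    force_noise_sd: float = 0.3  # N, per-sample channel force noise
    mpe_scale: float = 0.015  # m, naive (zero-compensation) MPE amplitude
    mpe_noise_sd: float = 0.002  # m, trial-to-trial MPE amplitude jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.asymptote <= 1.0:
            raise ValueError("asymptote must lie in [0, 1]")
        if self.rate_trials <= 0:
            raise ValueError("rate constant must be positive")

    def compensation_at(self, n_exposure: float) -> float:
        return self.asymptote + (self.initial - self.asymptote) * float(
            np.exp(-n_exposure / self.rate_trials)
        )


def _adaptation_profile(dt: float = 0.001):
    return min_jerk_profile(ADAPT_DISTANCE_M, ADAPT_DURATION_S, dt)


def make_channel_log(
    truth: GroundTruth,
    condition: KinematicCondition,
    seed: int,
    trained: KinematicCondition | None = None,
    context: str = "cw",
    compensation: float | None = None,
    spec: TrialSpec | None = None,
    dt: float = 0.001,
) -> TrialLog:
    """Synthetic channel-trial log with a planted compensation fraction.

    The hand path is clamped exactly to the via-to-target line with a
    minimum-jerk forward velocity; the perpendicular environment force is
    c_eff * k * v(t) plus Gaussian noise, where c_eff is ``compensation``
    (default ``truth.asymptote``) times the recall weight of ``condition``
    relative to ``trained`` (1 if no trained condition is given).
    """
    rng = np.random.default_rng(seed)
    prof = _adaptation_profile(dt)
    n = prof.positions.shape[0]
    c = truth.asymptote if compensation is None else compensation
    if trained is not None:
        c = c * recall_weight(condition, trained, truth.tuning)
    k = signed_k(context)
    v_fwd = prof.velocities[:, 0]  # profile laid along +x
    f_perp = c * k * v_fwd
    if truth.force_noise_sd > 0:
        f_perp = f_perp + rng.normal(0.0, truth.force_noise_sd, size=n)
    f_env = np.column_stack([np.zeros(n), f_perp])
    if spec is None:
        spec = TrialSpec(
            day=1,
            phase="generalization",
            block_index=0,
            trial_type="channel",
            field_direction=context,
            target_angle=0.0,
            lead_in=condition,
            is_transfer_probe=False,
            is_reversed_probe=condition.modality == "reversed_visual",
            condition_index=None,
        )
    return TrialLog(
        dt=dt,
        phase=np.full(n, PHASE_CODES["adaptation"], dtype=np.int8),
        pos=prof.positions,
        vel=prof.velocities,
        f_cmd=-f_env,
        f_env=f_env,
        spec=spec,
    )


def make_mpe_log(
    mpe_m: float,
    seed: int,
    context: str = "none",
    noise_sd: float = 0.0,
    spec: TrialSpec | None = None,
    dt: float = 0.001,
) -> TrialLog:
    """Synthetic field/null log whose sign-corrected MPE is planted.

    The path is the straight minimum-jerk adaptation path plus a smooth
    perpendicular bump A*sin(pi*tau)**2 in the direction the field pushes
    (left normal for CCW, right for CW); A = mpe_m + Gaussian jitter.
    """
    rng = np.random.default_rng(seed)
    prof = _adaptation_profile(dt)
    n = prof.positions.shape[0]
    amp = mpe_m + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    tau = np.linspace(0.0, 1.0, n)
    side = 1.0 if context != "cw" else -1.0  # push direction = sign(k) * n
    bump = side * amp * np.sin(np.pi * tau) ** 2
    pos = prof.positions.copy()
    pos[:, 1] += bump
    vel = prof.velocities.copy()
    vel[:, 1] += np.gradient(bump, dt)
    if spec is None:
        spec = TrialSpec(
            day=1,
            phase="exposure",
            block_index=0,
            trial_type="field" if context in ("cw", "ccw") else "null",
            field_direction=context,
            target_angle=0.0,
            lead_in=KinematicCondition(0.1, 0.7),
        )
    zeros = np.zeros((n, 2))
    return TrialLog(
        dt=dt,
        phase=np.full(n, PHASE_CODES["adaptation"], dtype=np.int8),
        pos=pos,
        vel=vel,
        f_cmd=zeros,
        f_env=zeros.copy(),
        spec=spec,
    )


@dataclass
class SyntheticDataset:
    """Lazily generated multi-participant synthetic experiment."""

    truth: GroundTruth
    config: ProtocolConfig
    n_participants: int
    seed: int

    @property
    def manifest(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "seed": self.seed,
            "trained_modality": self.config.trained_modality,
            "truth": {
                **{
                    k: v
                    for k, v in asdict(self.truth).items()
                    if not isinstance(v, dict)
                },
            },
        }

    def schedule(self, participant: int) -> Schedule:
        return build_schedule(self.config, participant, seed=self.seed)

    def iter_logs(self, participant: int):
        """Yield (TrialSpec, TrialLog) in protocol order for one participant.

        Compensation on each channel trial is the learning curve evaluated
        at the cued context's running field-trial count, scaled by the
        probe's recall weight; field/null MPE amplitudes follow
        mpe_scale * (1 - compensation).
        """
        sched = self.schedule(participant)
        trained = sched.trials[0].lead_in  # training kinematics, trained modality
        trained = KinematicCondition(
            distance=trained.distance,
            duration=trained.duration,
            modality=self.config.trained_modality,
        )
        n_exposure = {"cw": 0, "ccw": 0}
        ss = np.random.SeedSequence([self.seed, participant])
        trial_seeds = ss.generate_state(len(sched.trials))
        for i, t in enumerate(sched.trials):
            ctx = field_context(
                t.target_angle, t.lead_in.lead_in_angle_deg, sched.counterbalanced
            )
            s = int(trial_seeds[i] % (2**31 - 1))
            if t.trial_type == "channel":
                c = self.truth.compensation_at(n_exposure[ctx])
                log = make_channel_log(
                    self.truth,
                    t.lead_in,
                    seed=s,
                    trained=trained,
                    context=ctx,
                    compensation=c,
                    spec=t,
                )
            else:
                if t.trial_type == "field":
                    c = self.truth.compensation_at(n_exposure[ctx])
                    mpe = self.truth.mpe_scale * (1.0 - c)
                    n_exposure[ctx] += 1
                else:
                    mpe = 0.0
                log = make_mpe_log(
                    mpe,
                    seed=s,
                    context=ctx if t.trial_type == "field" else "none",
                    noise_sd=self.truth.mpe_noise_sd,
                    spec=t,
                )
            yield t, log

    def write(self, out_dir) -> None:
        """Write the dataset as CSV logs + JSON sidecars, one directory per
        participant, plus a manifest.json recording all ground truths."""
        import json
        import os

        from .environment import write_log

        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2)
        for p in range(self.n_participants):
            pdir = os.path.join(out_dir, f"participant_{p:02d}")
            os.makedirs(pdir, exist_ok=True)
            for i, (_, log) in enumerate(self.iter_logs(p)):
                write_log(log, os.path.join(pdir, f"trial_{i:04d}"))


def make_experiment_dataset(
    config: ProtocolConfig | None,
    truth: GroundTruth,
    n_participants: int,
    seed: int,
    out_dir=None,
) -> SyntheticDataset:
    """Build a synthetic multi-participant dataset; optionally write it out."""
    ds = SyntheticDataset(
        truth=truth,
        config=config or ProtocolConfig(),
        n_participants=n_participants,
        seed=seed,
    )
    if out_dir is not None:
        ds.write(out_dir)
    return ds
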