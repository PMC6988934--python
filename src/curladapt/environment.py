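"""Single-trial dynamics: point-mass hand, curl field, channel, controller.

One trial is a two-part movement: a lead-in from a start location to the
central via point (hand-transported for passive lead-ins, cursor-only for
visual ones), a short dwell, then an 18 cm adaptation movement to the
target.  During the adaptation movement the environment applies either
nothing (null), a velocity-dependent curl field

    F = k * [[0, -1], [1, 0]] @ v,        k = +/-16 N m^-1 s,

or a stiff spring-damper channel (6000 N/m, 30 N m^-1 s) clamping lateral
motion to the straight via-to-target line.  The hand is a planar point
mass driven by a PD controller tracking the desired minimum-jerk
trajectory (plus inverse-dynamics feedforward of the desired acceleration)
and by the learned compensatory feedforward, which is the recalled
compensation fraction times the negated curl force evaluated at the
desired velocity.  On channel trials the tracking error is projected onto
the channel direction: the clamp removes perceived lateral error, so there
is no error-induced lateral feedback and the force pressed into the wall
reads out the predictive compensation.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .kinematics import KinematicCondition, min_jerk_profile
from .memory import MemoryState, predict_compensation, update
from .protocol import (
    ADAPT_DISTANCE_M,
    ADAPT_DURATION_S,
    Schedule,
    TrialSpec,
    field_context,
)

__all__ = [
    "CURL_K",
    "FieldSpec",
    "PlantParams",
    "TrialLog",
    "curl_force",
    "channel_force",
    "simulate_trial",
    "run_schedule",
    "ExperimentResult",
    "signed_k",
    "write_log",
    "read_log",
]

#: Magnitude of the curl-field constant (N m^-1 s).
CURL_K = 16.0
CHANNEL_SPRING = 6000.0  # N/m
CHANNEL_DAMPING = 30.0  # N m^-1 s

PHASE_CODES = {"lead_in": 0, "dwell": 1, "adaptation": 2}
PHASE_NAMES = {v: k for k, v in PHASE_CODES.items()}


def signed_k(direction: str, magnitude: float = CURL_K) -> float:
    """Signed field constant: CW curls rightward of velocity (k < 0)."""
    if direction == "cw":
        return -magnitude
    if direction == "ccw":
        return magnitude
    raise ValueError(f"unknown field direction {direction!r}")


@dataclass(frozen=True)
class FieldSpec:
    """Environment dynamics for the adaptation movement."""

    kind: str = "null"  # null | curl | channel
    k: float = CURL_K  # signed, N m^-1 s
    spring: float = CHANNEL_SPRING
    damping: float = CHANNEL_DAMPING
    channel_path: tuple = ((0.0, 0.0), (ADAPT_DISTANCE_M, 0.0))

    def __post_init__(self) -> None:
        if self.kind not in ("null", "curl", "channel"):
            raise ValueError(f"unknown field kind {self.kind!r}")


@dataclass(frozen=True)
class PlantParams:
    """Point-mass hand and PD tracking controller.

    The experiment does not model the arm; these are generic values for a
    planar point-mass simulation of this paradigm.
    """

    mass: float = 1.5  # kg
    fb_stiffness: float = 700.0  # N/m
    fb_damping: float = 40.0  # N s/m
    motor_noise_sd: float = 0.2  # N, white force noise on the command

    def __post_init__(self) -> None:
        if min(self.mass, self.fb_stiffness, self.fb_damping) <= 0:
            raise ValueError("mass and feedback gains must be positive")
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be non-negative")


@dataclass
class TrialLog:
    """1 kHz time series of one simulated trial.

    phase is an int8 code per sample (0 lead_in, 1 dwell, 2 adaptation);
    f_cmd is the controller command, f_env the environment force on the
    hand.  The force the hand presses into a channel wall is ``-f_env``.
    """

    dt: float
    phase: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    f_cmd: np.ndarray
    f_env: np.ndarray
    spec: TrialSpec | None = None

    def __len__(self) -> int:
        return self.pos.shape[0]

    @property
    def t_ms(self) -> np.ndarray:
        return np.round(np.arange(len(self)) * self.dt * 1000.0).astype(int)

    def phase_slice(self, name: str) -> slice:
        idx = np.flatnonzero(self.phase == PHASE_CODES[name])
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t_ms,
                "phase": [PHASE_NAMES[int(p)] for p in self.phase],
                "x_m": self.pos[:, 0],
                "y_m": self.pos[:, 1],
                "vx_ms": self.vel[:, 0],
                "vy_ms": self.vel[:, 1],
                "fx_cmd_N": self.f_cmd[:, 0],
                "fy_cmd_N": self.f_cmd[:, 1],
                "fx_env_N": self.f_env[:, 0],
                "fy_env_N": self.f_env[:, 1],
            }
        )


def write_log(log: TrialLog, path_base: str) -> None:
    """Write a trial log as CSV plus a JSON sidecar of its TrialSpec."""
    log.to_frame().to_csv(path_base + ".csv", index=False)
    if log.spec is not None:
        meta = asdict(log.spec)
        with open(path_base + ".json", "w") as fh:
            json.dump(meta, fh)


def read_log(path_base: str) -> TrialLog:
    df = pd.read_csv(path_base + ".csv")
    spec = None
    if os.path.exists(path_base + ".json"):
        with open(path_base + ".json") as fh:
            meta = json.load(fh)
        meta["lead_in"] = KinematicCondition(**meta["lead_in"])
        spec = TrialSpec(**meta)
    t = df["t_ms"].to_numpy()
    dt = (t[1] - t[0]) / 1000.0 if len(t) > 1 else 0.001
    return TrialLog(
        dt=dt,
        phase=np.array([PHASE_CODES[p] for p in df["phase"]], dtype=np.int8),
        pos=df[["x_m", "y_m"]].to_numpy(),
        vel=df[["vx_ms", "vy_ms"]].to_numpy(),
        f_cmd=df[["fx_cmd_N", "fy_cmd_N"]].to_numpy(),
        f_env=df[["fx_env_N", "fy_env_N"]].to_numpy(),
        spec=spec,
    )


def curl_force(k: float, velocity) -> np.ndarray:
    """Curl-field force F = k * [[0,-1],[1,0]] @ v = (-k*vy, k*vx).

    ``velocity`` may be one planar vector or an (n, 2) array.
    """
    v = np.asarray(velocity, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity must be finite")
    return np.stack([-k * v[..., 1], k * v[..., 0]], axis=-1)


def channel_force(position, velocity, spec: FieldSpec) -> np.ndarray:
    """Spring-damper wall force, purely perpendicular to the channel line."""
    p0 = np.asarray(spec.channel_path[0], dtype=float)
    p1 = np.asarray(spec.channel_path[1], dtype=float)
    axis = p1 - p0
    length = math.hypot(*axis)
    if length < 1e-12:
        raise ValueError("degenerate channel path")
    u = axis / length
    n = np.array([-u[1], u[0]])
    pos = np.asarray(position, dtype=float)
    vel = np.asarray(velocity, dtype=float)
    d_perp = (pos - p0) @ n
    v_perp = vel @ n
    f = -(spec.spring * d_perp + spec.damping * v_perp)
    return np.multiply.outer(f, n)


# ---------------------------------------------------------------------------
# fixed-step semi-implicit Euler integration of the adaptation movement

_ENV_NULL, _ENV_CURL, _ENV_CHANNEL = 0, 1, 2


def _integrate_core(
    pd_xy, vd_xy, ad_xy, noise_xy,
    dt, mass, kp, kv,
    c_ff, k_ff, env_kind, k_env, spring, damping, ux, uy,
):
    n = pd_xy.shape[0]
    pos = np.empty((n, 2))
    vel = np.empty((n, 2))
    fcmd = np.empty((n, 2))
    fenv = np.empty((n, 2))
    nx, ny = -uy, ux
    x = pd_xy[0, 0]
    y = pd_xy[0, 1]
    vx = 0.0
    vy = 0.0
    for i in range(n):
        ex = pd_xy[i, 0] - x
        ey = pd_xy[i, 1] - y
        evx = vd_xy[i, 0] - vx
        evy = vd_xy[i, 1] - vy
        if env_kind == _ENV_CHANNEL:
            # clamp removes perceived lateral error: feedback along the
            # channel direction only
            s = ex * ux + ey * uy
            ex, ey = s * ux, s * uy
            s = evx * ux + evy * uy
            evx, evy = s * ux, s * uy
        # learned feedforward: -c * curl(k_trained, v_desired)
        ffx = c_ff * k_ff * vd_xy[i, 1]
        ffy = -c_ff * k_ff * vd_xy[i, 0]
        fcx = kp * ex + kv * evx + mass * ad_xy[i, 0] + ffx + noise_xy[i, 0]
        fcy = kp * ey + kv * evy + mass * ad_xy[i, 1] + ffy + noise_xy[i, 1]
        if env_kind == _ENV_CURL:
            fex = -k_env * vy
            fey = k_env * vx
        elif env_kind == _ENV_CHANNEL:
            dp = x * nx + y * ny
            vp = vx * nx + vy * ny
            f = -(spring * dp + damping * vp)
            fex = f * nx
            fey = f * ny
        else:
            fex = 0.0
            fey = 0.0
        pos[i, 0] = x
        pos[i, 1] = y
        vel[i, 0] = vx
        vel[i, 1] = vy
        fcmd[i, 0] = fcx
        fcmd[i, 1] = fcy
        fenv[i, 0] = fex
        fenv[i, 1] = fey
        ax = (fcx + fex) / mass
        ay = (fcy + fey) / mass
        vx += ax * dt
        vy += ay * dt
        x += vx * dt
        y += vy * dt
    return pos, vel, fcmd, fenv


try:  # pragma: no cover - exercised implicitly
    import numba

    _integrate = numba.njit(cache=False)(_integrate_core)
except Exception:  # pragma: no cover
    _integrate = _integrate_core


def _unit(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a)])


def simulate_trial(
    spec: TrialSpec,
    memory: MemoryState,
    plant: PlantParams | None = None,
    seed: int | None = None,
    dt: float = 0.001,
    field_spec: FieldSpec | None = None,
    cued_context: str | None = None,
    dwell_ms: float | None = None,
) -> TrialLog:
    """Simulate one complete trial and return its 1 kHz log.

    The lead-in phase replays the condition's minimum-jerk profile (hand
    motion for passive lead-ins; hand stationary at the via point for
    visual and reversed-visual ones).  Dwell time is drawn uniformly from
    0-250 ms.  The adaptation phase integrates the point-mass dynamics
    with the environment given by ``spec.trial_type`` (or an explicit
    ``field_spec`` override).

    ``cued_context`` names the memory context recalled by the lead-in;
    it defaults to ``spec.field_direction`` and must be supplied for null
    trials if a feedforward is to be expressed.
    """
    plant = plant or PlantParams()
    if plant.motor_noise_sd > 0 and seed is None:
        raise ValueError("seed is required when motor_noise_sd > 0")
    rng = np.random.default_rng(seed)

    via = np.zeros(2)
    u_target = _unit(spec.target_angle)
    target = ADAPT_DISTANCE_M * u_target

    # --- lead-in phase (replayed, not controlled) ---
    lead = spec.lead_in
    n_lead = int(round(lead.duration / dt)) + 1
    if lead.modality == "passive":
        prof = min_jerk_profile(
            lead.distance,
            lead.duration,
            dt,
            origin=lead.distance * _unit(lead.lead_in_angle_deg),
            heading_deg=(lead.lead_in_angle_deg + 180.0) % 360.0,
        )
        lead_pos, lead_vel = prof.positions, prof.velocities
    else:
        # visual / reversed-visual: the hand waits at the via point
        lead_pos = np.tile(via, (n_lead, 1))
        lead_vel = np.zeros((n_lead, 2))

    # --- dwell at the via point ---
    if dwell_ms is None:
        dwell_ms = float(rng.uniform(0.0, 250.0))
    n_dwell = int(round(dwell_ms / 1000.0 / dt))
    dwell_pos = np.tile(via, (n_dwell, 1))
    dwell_vel = np.zeros((n_dwell, 2))

    # --- adaptation phase ---
    desired = min_jerk_profile(
        ADAPT_DISTANCE_M, ADAPT_DURATION_S, dt, origin=via,
        heading_deg=spec.target_angle,
    )
    n_adapt = desired.positions.shape[0]

    context = cued_context or (
        spec.field_direction if spec.field_direction in ("cw", "ccw") else None
    )
    if context is not None and context in memory.trained:
        c_ff = predict_compensation(memory, lead, context)
        k_ff = signed_k(context)
    else:
        c_ff = 0.0
        k_ff = 0.0

    if field_spec is None:
        if spec.trial_type == "field":
            field_spec = FieldSpec(kind="curl", k=signed_k(spec.field_direction))
        elif spec.trial_type == "channel":
            field_spec = FieldSpec(
                kind="channel", channel_path=(tuple(via), tuple(target))
            )
        else:
            field_spec = FieldSpec(kind="null")

    env_kind = {"null": _ENV_NULL, "curl": _ENV_CURL, "channel": _ENV_CHANNEL}[
        field_spec.kind
    ]
    if plant.motor_noise_sd > 0:
        noise = rng.normal(0.0, plant.motor_noise_sd, size=(n_adapt, 2))
    else:
        noise = np.zeros((n_adapt, 2))

    pos_a, vel_a, fcmd_a, fenv_a = _integrate(
        desired.positions,
        desired.velocities,
        desired.accelerations,
        noise,
        dt,
        plant.mass,
        plant.fb_stiffness,
        plant.fb_damping,
        c_ff,
        k_ff,
        env_kind,
        field_spec.k,
        field_spec.spring,
        field_spec.damping,
        u_target[0],
        u_target[1],
    )

    n_total = n_lead + n_dwell + n_adapt
    phase = np.concatenate(
        [
            np.zeros(n_lead, dtype=np.int8),
            np.ones(n_dwell, dtype=np.int8),
            np.full(n_adapt, 2, dtype=np.int8),
        ]
    )
    pos = np.concatenate([lead_pos, dwell_pos, pos_a])
    vel = np.concatenate([lead_vel, dwell_vel, vel_a])
    f_cmd = np.zeros((n_total, 2))
    f_env = np.zeros((n_total, 2))
    f_cmd[n_lead + n_dwell :] = fcmd_a
    f_env[n_lead + n_dwell :] = fenv_a
    return TrialLog(
        dt=dt, phase=phase, pos=pos, vel=vel, f_cmd=f_cmd, f_env=f_env, spec=spec
    )


@dataclass
class ExperimentResult:
    """Outcome of a closed-loop run over a schedule."""

    trials: pd.DataFrame
    channel_logs: list
    memory: MemoryState


def _signed_lateral_error(log: TrialLog, k_env: float) -> float:
    """Extreme perpendicular deviation of the adaptation path, signed so a
    positive value means the field pushed the hand (under-compensation)."""
    sl = log.phase_slice("adaptation")
    pos = log.pos[sl]
    u = _unit(log.spec.target_angle)
    n = np.array([-u[1], u[0]])
    dev = pos @ n
    ext = dev[np.argmax(np.abs(dev))]
    return float(ext * np.sign(k_env)) if k_env != 0 else float(ext)


def run_schedule(
    schedule: Schedule,
    memory: MemoryState,
    plant: PlantParams | None = None,
    seed: int = 0,
    error_ref: float = 0.07,
    forgetting_trials: int = 200,
    keep_channel_logs: bool = True,
) -> ExperimentResult:
    """Run the full two-day protocol in closed loop.

    Each field trial is simulated with the current memory, its simulated
    sign-corrected lateral error (normalized by ``error_ref`` metres and
    clipped to [-1, 1]) drives the state-space update for the cued
    context.  Channel and null trials never update the memory.  Between
    days the memory decays by retention**forgetting_trials.
    """
    plant = plant or PlantParams()
    rng = np.random.default_rng(seed)
    trial_seeds = rng.integers(0, 2**31 - 1, size=len(schedule.trials))
    rows = []
    channel_logs: list[TrialLog] = []
    current_day = schedule.trials[0].day if schedule.trials else 1
    for i, t in enumerate(schedule.trials):
        if t.day != current_day:
            memory = memory.apply_forgetting(forgetting_trials)
            current_day = t.day
        ctx = field_context(
            t.target_angle, t.lead_in.lead_in_angle_deg, schedule.counterbalanced
        )
        log = simulate_trial(
            t, memory, plant, seed=int(trial_seeds[i]), cued_context=ctx
        )
        row = {
            "trial": i,
            "day": t.day,
            "phase": t.phase,
            "block": t.block_index,
            "trial_type": t.trial_type,
            "context": ctx,
            "condition_index": t.condition_index,
            "is_transfer_probe": t.is_transfer_probe,
            "is_reversed_probe": t.is_reversed_probe,
            "w_cw": memory.w_cw,
            "w_ccw": memory.w_ccw,
        }
        if t.trial_type == "field":
            k_env = signed_k(t.field_direction)
            err = _signed_lateral_error(log, k_env)
            row["mpe_m"] = err
            e_norm = float(np.clip(err / error_ref, -1.0, 1.0))
            memory = update(memory, e_norm, ctx, probe=t.lead_in)
        elif t.trial_type == "null":
            row["mpe_m"] = _signed_lateral_error(log, 0.0)
        else:
            if keep_channel_logs:
                channel_logs.append(log)
        rows.append(row)
    return ExperimentResult(
        trials=pd.DataFrame(rows), channel_logs=channel_logs, memory=memory
    )
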