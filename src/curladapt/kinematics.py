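"""Minimum-jerk trajectories and the kinematic lead-in condition grid.

Lead-in movements are point-to-point minimum-jerk motions: position along
the movement direction follows d*(10*tau**3 - 15*tau**4 + 6*tau**5) with
tau = t/T, which starts and ends at rest and peaks at speed 1.875*d/T at
the temporal midpoint.  The condition grid enumerates the lead-in probes
used to map kinematic generalization of contextual motor memory: 15
within-modality conditions spanning 3-20 cm and 210-1400 ms, one
opposite-modality transfer probe and one reversed-visual ("lead-away")
probe, both at the training kinematics (10 cm, 700 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PEAK_SPEED_FACTOR",
    "KinematicCondition",
    "TrajectoryProfile",
    "min_jerk_profile",
    "peak_speed",
    "condition_grid",
    "grid_to_frame",
    "TRAINING_DISTANCE_M",
    "TRAINING_DURATION_S",
]

#: Peak speed of a minimum-jerk movement is 1.875 * distance / duration
#: (maximum of 30*tau**2 - 60*tau**3 + 30*tau**4 at tau = 1/2 is 15/8).
PEAK_SPEED_FACTOR = 1.875

TRAINING_DISTANCE_M = 0.10
TRAINING_DURATION_S = 0.70

MODALITIES = ("passive", "visual", "reversed_visual")


def peak_speed(distance: float, duration: float) -> float:
    """Peak speed (m/s) of a minimum-jerk movement of given extent.

    Parameters
    ----------
    distance : float
        Movement extent in metres, > 0.
    duration : float
        Movement time in seconds, > 0.
    """
    if distance <= 0 or duration <= 0:
        raise ValueError(
            f"distance and duration must be positive, got {distance}, {duration}"
        )
    return PEAK_SPEED_FACTOR * distance / duration


@dataclass(frozen=True)
class KinematicCondition:
    """One lead-in condition: extent, timing, modality and approach angle.

    ``lead_in_angle_deg`` is the angular position of the lead-in start
    location relative to the central via point (counter-clockwise from +x);
    the lead-in moves from that start location to the via point.  ``None``
    means the condition is direction-agnostic (as in the abstract grid,
    before it is crossed with the two start locations).
    """

    distance: float
    duration: float
    modality: str = "passive"
    lead_in_angle_deg: float | None = None
    is_training: bool = False

    def __post_init__(self) -> None:
        if self.distance <= 0 or self.duration <= 0:
            raise ValueError("distance and duration must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def peak_speed(self) -> float:
        """Peak speed in m/s, 1.875 * distance / duration."""
        return peak_speed(self.distance, self.duration)

    def with_angle(self, angle_deg: float) -> "KinematicCondition":
        return replace(self, lead_in_angle_deg=angle_deg)


@dataclass(frozen=True)
class TrajectoryProfile:
    """Sampled planar trajectory at fixed time step ``dt``."""

    dt: float
    positions: np.ndarray  # (n, 2) m
    velocities: np.ndarray  # (n, 2) m/s
    accelerations: np.ndarray  # (n, 2) m/s^2

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.positions.shape[0]) * self.dt

    @property
    def speeds(self) -> np.ndarray:
        return np.hypot(self.velocities[:, 0], self.velocities[:, 1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation matching the trial-log column schema."""
        return pd.DataFrame(
            {
                "t_ms": np.round(self.times * 1000.0).astype(int),
                "x_m": self.positions[:, 0],
                "y_m": self.positions[:, 1],
                "vx": self.velocities[:, 0],
                "vy": self.velocities[:, 1],
            }
        )


def _min_jerk_1d(t: np.ndarray, distance: float, duration: float):
    """Scalar minimum-jerk position/velocity/acceleration along the path."""
    tau = np.clip(t / duration, 0.0, 1.0)
    pos = distance * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    vel = distance / duration * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    acc = distance / duration**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)
    return pos, vel, acc


def min_jerk_profile(
    distance: float,
    duration: float,
    dt: float = 0.001,
    origin: Sequence[float] = (0.0, 0.0),
    heading_deg: float = 0.0,
) -> TrajectoryProfile:
    """Straight-line minimum-jerk movement sampled at ``dt``.

    The movement starts at rest at ``origin`` and ends at rest
    ``distance`` metres along ``heading_deg`` (counter-clockwise from +x).
    The perpendicular component is identically zero.

    Raises
    ------
    ValueError
        If any of distance, duration, dt is non-positive or dt is too
        coarse (dt > duration / 10) to resolve the profile.
    """
    if distance <= 0 or duration <= 0 or dt <= 0:
        raise ValueError("distance, duration and dt must be positive")
    if dt > duration / 10:
        raise ValueError(f"dt={dt} too coarse for duration {duration}")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    pos1, vel1, acc1 = _min_jerk_1d(t, distance, duration)
    theta = math.radians(heading_deg)
    u = np.array([math.cos(theta), math.sin(theta)])
    origin = np.asarray(origin, dtype=float)
    return TrajectoryProfile(
        dt=dt,
        positions=origin + pos1[:, None] * u,
        velocities=vel1[:, None] * u,
        accelerations=acc1[:, None] * u,
    )


# The 15 within-modality generalization conditions: (duration s, distance m).
# The first entry is the training condition (10 cm, 700 ms, 26.8 cm/s); the
# rest sample iso-speed, iso-duration and iso-distance lines through it,
# spanning 3-20 cm, 210-1400 ms and peak speeds 8.04-53.57 cm/s.
_GRID_DUR_DIST: tuple[tuple[float, float], ...] = (
    (0.70, 0.10),  # training
    (1.40, 0.20),
    (1.05, 0.15),
    (0.42, 0.06),
    (0.21, 0.03),
    (1.40, 0.10),
    (1.05, 0.10),
    (0.42, 0.10),
    (0.35, 0.10),
    (0.70, 0.20),
    (0.70, 0.15),
    (0.70, 0.06),
    (0.70, 0.03),
    (1.05, 0.20),
    (0.35, 0.03),
)


def condition_grid(trained_modality: str = "passive") -> list[KinematicCondition]:
    """The 17 channel-trial lead-in conditions for one experiment.

    Returns the 15 within-modality generalization conditions (the first of
    which is the training condition), the opposite-modality transfer probe
    and the reversed-visual probe, in a stable order.  Crossed with the two
    lead-in start locations these form the 34 distinct generalization
    probes.
    """
    if trained_modality not in ("passive", "visual"):
        raise ValueError("trained_modality must be 'passive' or 'visual'")
    other = "visual" if trained_modality == "passive" else "passive"
    grid = [
        KinematicCondition(
            distance=d,
            duration=T,
            modality=trained_modality,
            is_training=(i == 0),
        )
        for i, (T, d) in enumerate(_GRID_DUR_DIST)
    ]
    grid.append(
        KinematicCondition(
            distance=TRAINING_DISTANCE_M,
            duration=TRAINING_DURATION_S,
            modality=other,
        )
    )
    grid.append(
        KinematicCondition(
            distance=TRAINING_DISTANCE_M,
            duration=TRAINING_DURATION_S,
            modality="reversed_visual",
        )
    )
    return grid


def grid_to_frame(grid: list[KinematicCondition]) -> pd.DataFrame:
    """Condition grid as a table (condition, duration_ms, distance_cm, peak_speed_cms)."""
    return pd.DataFrame(
        {
            "condition": np.arange(len(grid)),
            "modality": [c.modality for c in grid],
            "is_training": [c.is_training for c in grid],
            "duration_ms": [round(c.duration * 1000) for c in grid],
            "distance_cm": [c.distance * 100 for c in grid],
            "peak_speed_cms": [c.peak_speed * 100 for c in grid],
        }
    )
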