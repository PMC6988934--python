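"""Kinematic-error and force-compensation metrics from trial logs.

Two measures quantify adaptation.  On null and curl-field trials, the
maximum perpendicular error (MPE): the largest deviation of the adaptation
hand path from the straight line joining its start to its end, signed and
sign-corrected by field direction so opposing-field trials average
together.  On channel trials, force compensation: the slope of the
perpendicular channel force regressed (through the origin, by default)
against the forward velocity scaled by the curl-field constant, expressed
as percent of perfect field cancellation.

Sign conventions: the perpendicular force sample is the channel's reaction
force projected on the left normal of the channel (equal and opposite to
the force the hand presses into the wall), and the regressor is k times
forward velocity with k signed; with these choices a hand pressing against
where the field would push yields positive compensation for both field
directions, with no post-hoc sign flip.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .environment import TrialLog
from .kinematics import KinematicCondition
from .memory import TuningParams

__all__ = [
    "NotApplicableError",
    "InsufficientDataError",
    "UnstableRatioError",
    "CompensationEstimate",
    "GeneralizationSurface",
    "compute_mpe",
    "block_average",
    "block_average_mpe",
    "estimate_compensation",
    "pair_average",
    "build_generalization_surface",
    "transfer_ratio",
    "fit_tuning_widths",
]

#: Radius within which the cursor counts as at a location: disk radius
#: (1.25 cm) minus cursor radius (0.5 cm).
CONTACT_RADIUS_M = 0.0075
MIN_WINDOW_SAMPLES = 50


class NotApplicableError(ValueError):
    """The metric does not apply to this trial type."""


class InsufficientDataError(ValueError):
    """Too few samples in the analysis window."""


class UnstableRatioError(ValueError):
    """Denominator too small for a meaningful ratio."""


def _path_frame(pos: np.ndarray):
    """Unit direction and left normal of the start-to-end line of a path."""
    axis = pos[-1] - pos[0]
    length = math.hypot(*axis)
    if length < 1e-9:
        raise InsufficientDataError("degenerate adaptation path")
    u = axis / length
    return u, np.array([-u[1], u[0]])


def compute_mpe(log: TrialLog, sign_correct: bool = True) -> float:
    """Signed maximum perpendicular error (m) of the adaptation movement.

    Deviation is measured from the straight line joining the first and
    last adaptation-phase samples, positive along the left normal of the
    movement direction.  With ``sign_correct`` the sign is flipped on CW
    trials so that being pushed by the field is positive in both contexts.
    Applies to null and field trials only.
    """
    if log.spec is not None and log.spec.trial_type == "channel":
        raise NotApplicableError("MPE is not defined on channel trials")
    sl = log.phase_slice("adaptation")
    pos = log.pos[sl]
    if pos.shape[0] < 2:
        raise InsufficientDataError("log has no adaptation phase")
    u, n = _path_frame(pos)
    dev = (pos - pos[0]) @ n
    ext = float(dev[np.argmax(np.abs(dev))])
    if sign_correct and log.spec is not None and log.spec.field_direction == "cw":
        ext = -ext
    return ext


def block_average(values, block_size: int = 8) -> pd.DataFrame:
    """Non-overlapping block means of a trial-ordered series.

    Returns one row per block with mean, SE (n-1 denominator), n, and a
    flag marking a trailing partial block.
    """
    values = np.asarray(list(values), dtype=float)
    rows = []
    for b, start in enumerate(range(0, len(values), block_size)):
        chunk = values[start : start + block_size]
        se = (
            float(np.std(chunk, ddof=1) / math.sqrt(len(chunk)))
            if len(chunk) > 1
            else float("nan")
        )
        rows.append(
            {
                "block": b,
                "mean": float(np.mean(chunk)),
                "se": se,
                "n": len(chunk),
                "partial": len(chunk) < block_size,
            }
        )
    return pd.DataFrame(
        rows, columns=["block", "mean", "se", "n", "partial"]
    )


def block_average_mpe(logs, block_size: int = 8) -> pd.DataFrame:
    """Blocked sign-corrected MPE over an ordered sequence of trial logs."""
    return block_average([compute_mpe(lg) for lg in logs], block_size)


@dataclass(frozen=True)
class CompensationEstimate:
    """Force compensation measured on one channel trial."""

    percent: float
    slope: float
    residual_var: float
    n_samples: int
    condition: KinematicCondition | None = None
    condition_index: int | None = None
    context: str | None = None
    is_transfer_probe: bool = False
    is_reversed_probe: bool = False

    @property
    def flagged(self) -> bool:
        """True when the estimate falls outside the plausible [-50, 150] band."""
        return not (-50.0 <= self.percent <= 150.0)


def estimate_compensation(
    log: TrialLog, k: float, include_intercept: bool = False
) -> CompensationEstimate:
    """Regress perpendicular channel force on field-scaled forward velocity.

    The analysis window runs from the hand leaving the via point (first
    sample farther than 0.75 cm from the movement start) until it enters
    the target (first sample within 0.75 cm of the movement end),
    half-open.  The compensation percent is 100 times the regression
    slope; the regression passes through the origin unless
    ``include_intercept`` is set.
    """
    if log.spec is not None and log.spec.trial_type != "channel":
        raise NotApplicableError("compensation is estimated on channel trials")
    sl = log.phase_slice("adaptation")
    pos = log.pos[sl]
    vel = log.vel[sl]
    f_env = log.f_env[sl]
    if pos.shape[0] < 2:
        raise InsufficientDataError("log has no adaptation phase")
    u, n = _path_frame(pos)
    d_from_start = np.linalg.norm(pos - pos[0], axis=1)
    d_to_end = np.linalg.norm(pos - pos[-1], axis=1)
    out = np.flatnonzero(d_from_start > CONTACT_RADIUS_M)
    inn = np.flatnonzero(d_to_end < CONTACT_RADIUS_M)
    i0 = int(out[0]) if out.size else 0
    i1 = int(inn[0]) if inn.size else pos.shape[0]
    if i1 - i0 < MIN_WINDOW_SAMPLES:
        raise InsufficientDataError(
            f"analysis window has {i1 - i0} samples (< {MIN_WINDOW_SAMPLES})"
        )
    v_fwd = vel[i0:i1] @ u
    f_perp = f_env[i0:i1] @ n
    x = k * v_fwd
    if include_intercept:
        X = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(X, f_perp, rcond=None)
        slope = float(coef[0])
        resid = f_perp - X @ coef
    else:
        slope = float(x @ f_perp / (x @ x))
        resid = f_perp - slope * x
    spec = log.spec
    return CompensationEstimate(
        percent=100.0 * slope,
        slope=slope,
        residual_var=float(np.var(resid)),
        n_samples=i1 - i0,
        condition=spec.lead_in if spec is not None else None,
        condition_index=spec.condition_index if spec is not None else None,
        context=spec.field_direction if spec is not None else None,
        is_transfer_probe=bool(spec.is_transfer_probe) if spec else False,
        is_reversed_probe=bool(spec.is_reversed_probe) if spec else False,
    )


def _percent(e) -> float:
    return e.percent if isinstance(e, CompensationEstimate) else float(e)


def pair_average(estimates) -> np.ndarray:
    """Average consecutive sign-corrected channel-trial pairs.

    Sequential channel trials probe opposite field contexts; averaging
    each pair yields one compensation value per pair.  An odd trailing
    estimate is dropped with a warning.
    """
    vals = np.array([_percent(e) for e in estimates], dtype=float)
    if len(vals) % 2:
        warnings.warn("odd number of channel estimates; dropping the last")
        vals = vals[:-1]
    return vals.reshape(-1, 2).mean(axis=1)


@dataclass
class GeneralizationSurface:
    """Per-condition compensation summary over the kinematic probe grid."""

    table: pd.DataFrame  # condition_index, duration_s, distance_m, modality,
    # is_training, mean, se, n
    normalized: bool

    def at(self, condition_index: int) -> pd.Series:
        return self.table.set_index("condition_index").loc[condition_index]

    @property
    def range(self) -> float:
        """max - min of the per-condition means (within-modality grid only)."""
        grid = self.table[self.table["in_grid"]]
        return float(grid["mean"].max() - grid["mean"].min())


def build_generalization_surface(
    estimates: pd.DataFrame,
    trained_condition: KinematicCondition,
    normalize: bool = False,
) -> GeneralizationSurface:
    """Assemble the per-condition generalization surface.

    ``estimates`` is a tidy table with one row per channel trial and
    columns: participant, condition_index, duration_s, distance_m,
    modality, is_transfer, is_reversed, percent.  Per-participant means
    are computed first; with ``normalize`` each participant's values are
    scaled by 100 / (their trained-condition mean).  Missing conditions
    are flagged absent (NaN mean), never imputed.
    """
    required = {"participant", "condition_index", "percent"}
    if not required.issubset(estimates.columns):
        raise ValueError(f"estimates table needs columns {sorted(required)}")
    df = estimates.copy()
    per = (
        df.groupby(["participant", "condition_index"], as_index=False)
        .agg(
            percent=("percent", "mean"),
            duration_s=("duration_s", "first"),
            distance_m=("distance_m", "first"),
            modality=("modality", "first"),
            is_transfer=("is_transfer", "first"),
            is_reversed=("is_reversed", "first"),
        )
    )
    trained_idx = 0
    if normalize:
        base = (
            per[per["condition_index"] == trained_idx]
            .set_index("participant")["percent"]
        )
        per["percent"] = [
            100.0 * p / base.loc[pid] for pid, p in zip(per["participant"], per["percent"])
        ]
    agg = (
        per.groupby("condition_index", as_index=False)
        .agg(
            mean=("percent", "mean"),
            se=("percent", lambda s: s.std(ddof=1) / math.sqrt(len(s)) if len(s) > 1 else np.nan),
            n=("percent", "size"),
            duration_s=("duration_s", "first"),
            distance_m=("distance_m", "first"),
            modality=("modality", "first"),
            is_transfer=("is_transfer", "first"),
            is_reversed=("is_reversed", "first"),
        )
        .sort_values("condition_index")
        .reset_index(drop=True)
    )
    agg["is_training"] = (
        (agg["duration_s"] == trained_condition.duration)
        & (agg["distance_m"] == trained_condition.distance)
        & (agg["modality"] == trained_condition.modality)
    )
    agg["in_grid"] = ~(agg["is_transfer"] | agg["is_reversed"])
    return GeneralizationSurface(table=agg, normalized=normalize)


def transfer_ratio(probe_estimates, asymptote_estimates) -> float:
    """Cross-condition transfer scaled by the trained asymptote, in percent.

    ``asymptote_estimates`` should be the trained-condition compensation
    values from the final four analysis blocks.
    """
    asym = float(np.mean([_percent(e) for e in asymptote_estimates]))
    if asym <= 5.0:
        raise UnstableRatioError(f"asymptote {asym:.2f}% too small for a ratio")
    probe = float(np.mean([_percent(e) for e in probe_estimates]))
    return 100.0 * probe / asym


def fit_tuning_widths(
    surface: GeneralizationSurface, trained_condition: KinematicCondition
) -> dict:
    """Recover tuning widths from a (normalized) generalization surface.

    Fits the recall model - Gaussian in duration, Gaussian in peak speed,
    saturating half-Gaussian in distance - to the within-modality grid
    means by nonlinear least squares.  Returns sigma_duration (s),
    sigma_speed (m/s) and distance_halfwidth (m).
    """
    grid = surface.table[surface.table["in_grid"]]
    T = grid["duration_s"].to_numpy(float)
    d = grid["distance_m"].to_numpy(float)
    v = 1.875 * d / T
    y = grid["mean"].to_numpy(float)
    T0, d0 = trained_condition.duration, trained_condition.distance
    v0 = trained_condition.peak_speed

    def model(X, amp, s_T, s_v, hw):
        Tq, dq, vq = X
        g = (
            np.exp(-0.5 * ((Tq - T0) / s_T) ** 2)
            * np.exp(-0.5 * ((vq - v0) / s_v) ** 2)
            * np.where(
                dq >= d0, 1.0, np.exp(-0.5 * ((dq - d0) / hw) ** 2)
            )
        )
        return amp * g

    p0 = (float(np.max(y)), 0.5, 0.3, 0.06)
    bounds = ([1e-6, 1e-3, 1e-3, 1e-3], [np.inf, 10.0, 10.0, 1.0])
    popt, _ = curve_fit(model, (T, d, v), y, p0=p0, bounds=bounds, maxfev=20000)
    return {
        "amplitude": float(popt[0]),
        "sigma_duration": float(popt[1]),
        "sigma_speed": float(popt[2]),
        "distance_halfwidth": float(popt[3]),
    }
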