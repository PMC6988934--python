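"""MPE, compensation regression, pairing, surfaces and transfer ratios."""

import math

import numpy as np
import pandas as pd
import pytest

from curladapt.analysis import (
    CompensationEstimate,
    InsufficientDataError,
    NotApplicableError,
    UnstableRatioError,
    block_average,
    block_average_mpe,
    build_generalization_surface,
    compute_mpe,
    estimate_compensation,
    pair_average,
    transfer_ratio,
)
from curladapt.environment import signed_k
from curladapt.kinematics import KinematicCondition
from curladapt.memory import TuningParams, recall_weight
from curladapt.synthetic import GroundTruth, make_channel_log, make_mpe_log

TRAIN = KinematicCondition(0.10, 0.70, "passive", lead_in_angle_deg=225.0)
NOISELESS = GroundTruth(force_noise_sd=0.0, mpe_noise_sd=0.0)


class TestComputeMPE:
    def test_straight_path_is_zero(self):
        log = make_mpe_log(0.0, seed=0)
        assert compute_mpe(log) == pytest.approx(0.0, abs=1e-12)

    def test_planted_bump_amplitude(self):
        log = make_mpe_log(0.02, seed=0, context="ccw")
        assert compute_mpe(log) == pytest.approx(0.02, abs=1e-4)

    def test_mirror_trials_agree_after_sign_correction(self):
        cw = make_mpe_log(0.013, seed=1, context="cw")
        ccw = make_mpe_log(0.013, seed=1, context="ccw")
        # raw deviations are mirror images; sign correction aligns them
        assert compute_mpe(cw, sign_correct=False) == pytest.approx(
            -compute_mpe(ccw, sign_correct=False), abs=1e-9
        )
        assert compute_mpe(cw) == pytest.approx(compute_mpe(ccw), abs=1e-9)

    def test_isometry_invariance(self):
        log = make_mpe_log(0.015, seed=2, context="ccw")
        theta = 0.83
        R = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        moved = make_mpe_log(0.015, seed=2, context="ccw")
        moved.pos = log.pos @ R.T + np.array([0.3, -1.2])
        moved.vel = log.vel @ R.T
        assert compute_mpe(moved) == pytest.approx(compute_mpe(log), abs=1e-9)

    def test_channel_trial_rejected(self):
        log = make_channel_log(NOISELESS, TRAIN, seed=0)
        with pytest.raises(NotApplicableError):
            compute_mpe(log)


class TestBlockAverage:
    def test_constant_series(self):
        df = block_average([0.01] * 16, block_size=8)
        assert len(df) == 2
        assert df["mean"].tolist() == [0.01, 0.01]
        assert df["se"].tolist() == [0.0, 0.0]
        assert not df["partial"].any()

    def test_decaying_series_has_decreasing_block_means(self):
        vals = 0.02 * np.exp(-np.arange(96) / 20.0)
        df = block_average(vals, block_size=8)
        means = df["mean"].to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_empty_input(self):
        df = block_average([], block_size=8)
        assert len(df) == 0

    def test_trailing_partial_block_flagged(self):
        df = block_average(np.ones(11), block_size=8)
        assert df.iloc[-1]["partial"] and df.iloc[-1]["n"] == 3

    def test_from_logs(self):
        logs = [make_mpe_log(0.01, seed=i, context="ccw") for i in range(8)]
        df = block_average_mpe(logs)
        assert df.iloc[0]["mean"] == pytest.approx(0.01, abs=1e-4)


class TestEstimateCompensation:
    @pytest.mark.parametrize("c", [0.5, 1.0])
    def test_planted_slope_recovered_exactly(self, c):
        log = make_channel_log(NOISELESS, TRAIN, seed=0, compensation=c)
        est = estimate_compensation(log, signed_k("cw"))
        assert est.percent == pytest.approx(100 * c, abs=1e-9)
        assert not est.flagged

    def test_matches_closed_form_slope(self):
        """Regression equals sum(F*kv)/sum((kv)^2) over the same window."""
        truth = GroundTruth(force_noise_sd=0.3)
        log = make_channel_log(truth, TRAIN, seed=42, compensation=0.627)
        k = signed_k("cw")
        est = estimate_compensation(log, k)
        # independent recomputation of window and slope
        pos, vel, f = log.pos, log.vel, log.f_env
        d0 = np.linalg.norm(pos - pos[0], axis=1)
        d1 = np.linalg.norm(pos - pos[-1], axis=1)
        i0 = int(np.flatnonzero(d0 > 0.0075)[0])
        i1 = int(np.flatnonzero(d1 < 0.0075)[0])
        x = k * vel[i0:i1, 0]
        y = f[i0:i1, 1]
        assert est.slope == pytest.approx(float(np.sum(y * x) / np.sum(x * x)),
                                          abs=1e-10)

    def test_monte_carlo_noise_recovery(self):
        """Planted 62.7% with 0.3 N force noise: the mean recovered percent
        over many seeds is within one point of truth."""
        truth = GroundTruth(force_noise_sd=0.3)
        vals = [
            estimate_compensation(
                make_channel_log(truth, TRAIN, seed=i, compensation=0.627),
                signed_k("cw"),
            ).percent
            for i in range(300)
        ]
        assert np.mean(vals) == pytest.approx(62.7, abs=1.0)

    def test_both_field_directions_read_positive(self):
        for ctx in ("cw", "ccw"):
            log = make_channel_log(
                NOISELESS, TRAIN, seed=0, compensation=0.4, context=ctx
            )
            est = estimate_compensation(log, signed_k(ctx))
            assert est.percent == pytest.approx(40.0, abs=1e-9)

    def test_short_window_rejected(self):
        log = make_channel_log(NOISELESS, TRAIN, seed=0)
        short = make_channel_log(NOISELESS, TRAIN, seed=0)
        short.pos = log.pos[:200:4]
        short.vel = log.vel[:200:4]
        short.f_env = log.f_env[:200:4]
        short.f_cmd = log.f_cmd[:200:4]
        short.phase = log.phase[:200:4]
        with pytest.raises(InsufficientDataError):
            estimate_compensation(short, signed_k("cw"))

    def test_field_trial_rejected(self):
        log = make_mpe_log(0.01, seed=0, context="cw")
        with pytest.raises(NotApplicableError):
            estimate_compensation(log, signed_k("cw"))


class TestPairAverage:
    def test_simple_pair(self):
        assert pair_average([60.0, 70.0]).tolist() == [65.0]

    def test_opposite_raw_signs_cancel_after_correction(self):
        # raw lab-frame slopes of a CW/CCW pair have opposite signs; after
        # the per-context sign correction both read +c and average to c
        c = 44.0
        corrected = [c, c]
        assert pair_average(corrected).tolist() == [c]

    def test_odd_count_drops_last_with_warning(self):
        with pytest.warns(UserWarning):
            out = pair_average(np.arange(38.0 + 1))
        assert len(out) == 19


class TestGeneralizationSurface:
    @staticmethod
    def _estimates_table(percent_fn, participants=3):
        from curladapt.kinematics import condition_grid

        rows = []
        for p in range(participants):
            for i, c in enumerate(condition_grid("passive")):
                rows.append(
                    {
                        "participant": p,
                        "condition_index": i,
                        "duration_s": c.duration,
                        "distance_m": c.distance,
                        "modality": c.modality,
                        "is_transfer": c.modality == "visual",
                        "is_reversed": c.modality == "reversed_visual",
                        "percent": percent_fn(p, i, c),
                    }
                )
        return pd.DataFrame(rows)

    def test_flat_surface_normalizes_to_100(self):
        df = self._estimates_table(lambda p, i, c: 62.7)
        surf = build_generalization_surface(
            df, KinematicCondition(0.1, 0.7, "passive"), normalize=True
        )
        grid = surf.table[surf.table["in_grid"]]
        assert np.allclose(grid["mean"], 100.0)
        assert surf.range == pytest.approx(0.0)

    def test_planted_tuning_peaks_at_trained_cell(self):
        tuning = TuningParams()
        trained = KinematicCondition(0.1, 0.7, "passive")
        df = self._estimates_table(
            lambda p, i, c: 62.7 * recall_weight(c, trained, tuning)
        )
        surf = build_generalization_surface(df, trained, normalize=False)
        grid = surf.table[surf.table["in_grid"]]
        assert grid.loc[grid["mean"].idxmax(), "is_training"]

    def test_trained_cell_exactly_100_per_participant(self):
        rng = np.random.default_rng(0)
        df = self._estimates_table(
            lambda p, i, c: (50 + 10 * p) * (0.5 + 0.5 * (i == 0)), participants=1
        )
        surf = build_generalization_surface(
            df, KinematicCondition(0.1, 0.7, "passive"), normalize=True
        )
        assert surf.at(0)["mean"] == pytest.approx(100.0)


class TestTransferRatio:
    def test_scaling_by_asymptote(self):
        assert transfer_ratio([22.07], [62.7]) == pytest.approx(35.2, abs=0.01)

    def test_trivial_cases(self):
        assert transfer_ratio([0.0], [62.7]) == 0.0
        assert transfer_ratio([62.7], [62.7]) == pytest.approx(100.0)

    def test_unstable_asymptote_rejected(self):
        with pytest.raises(UnstableRatioError):
            transfer_ratio([10.0], [4.0])

    def test_accepts_estimate_objects(self):
        est = CompensationEstimate(
            percent=31.35, slope=0.3135, residual_var=0.0, n_samples=400
        )
        assert transfer_ratio([est], [62.7]) == pytest.approx(50.0)
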