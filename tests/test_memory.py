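"""Tuned recall, prediction and the single-rate state-space update."""

import dataclasses
import math

import pytest
from hypothesis import given, settings, strategies as st

from curladapt.kinematics import KinematicCondition, condition_grid
from curladapt.memory import (
    MemoryState,
    TuningParams,
    default_memory,
    predict_compensation,
    recall_weight,
    update,
)

TRAIN = KinematicCondition(0.10, 0.70, "passive")


class TestRecallWeight:
    def test_unity_at_trained_condition(self):
        assert recall_weight(TRAIN, TRAIN, TuningParams()) == pytest.approx(1.0)

    def test_one_sigma_duration_offset(self):
        tuning = TuningParams()
        sigma = tuning.sigma_duration["passive"]
        # stretch duration by one width while scaling distance to hold peak
        # speed (and keep distance above the trained value, where the
        # distance term saturates at 1): pure duration-Gaussian factor
        T = 0.70 + sigma
        probe = KinematicCondition(0.10 * T / 0.70, T, "passive")
        assert recall_weight(probe, TRAIN, tuning) == pytest.approx(
            math.exp(-0.5), rel=1e-9
        )

    def test_distance_saturates_above_trained(self):
        probe = dataclasses.replace(TRAIN, distance=0.20, duration=1.40)
        # speed matches training (26.8 cm/s); duration differs
        expected = math.exp(
            -0.5 * (0.70 / TuningParams().sigma_duration["passive"]) ** 2
        )
        assert recall_weight(probe, TRAIN, TuningParams()) == pytest.approx(expected)
        # doubling distance at matched duration/speed costs nothing
        probe2 = KinematicCondition(0.20, 1.40, "passive")
        assert recall_weight(probe2, TRAIN, TuningParams()) == recall_weight(
            probe, TRAIN, TuningParams()
        )

    def test_shorter_distance_reduces_recall(self):
        tuning = TuningParams()
        near = KinematicCondition(0.10, 0.70, "passive")
        short = KinematicCondition(0.05, 0.35, "passive")  # same peak speed
        assert recall_weight(short, TRAIN, tuning) < recall_weight(
            near, TRAIN, tuning
        )

    def test_modality_and_reversal_gains(self):
        tuning = TuningParams()
        visual_probe = dataclasses.replace(TRAIN, modality="visual")
        assert recall_weight(visual_probe, TRAIN, tuning) == pytest.approx(0.352)
        reversed_probe = dataclasses.replace(TRAIN, modality="reversed_visual")
        assert recall_weight(reversed_probe, TRAIN, tuning) == pytest.approx(0.227)

    def test_maximal_at_trained_over_probe_grid(self):
        tuning = TuningParams()
        all_w = [
            recall_weight(c, TRAIN, tuning) for c in condition_grid("passive")
        ]
        assert max(all_w) == pytest.approx(1.0)
        assert all_w.count(max(all_w)) == 1

    @given(
        st=st.floats(0.05, 2.0),
        sv=st.floats(0.05, 2.0),
        hw=st.floats(0.01, 0.5),
    )
    @settings(max_examples=50, derandomize=True)
    def test_bounded_and_peaked_for_any_widths(self, st, sv, hw):
        tuning = TuningParams(
            sigma_duration={"passive": st, "visual": st},
            sigma_speed={"passive": sv, "visual": sv},
            distance_halfwidth={"passive": hw, "visual": hw},
        )
        for c in condition_grid("passive"):
            w = recall_weight(c, TRAIN, tuning)
            assert 0.0 <= w <= 1.0
        assert recall_weight(TRAIN, TRAIN, tuning) == pytest.approx(1.0)

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            TuningParams(sigma_duration={"passive": -1.0, "visual": 0.7})
        with pytest.raises(ValueError):
            TuningParams(reversal_gain={"passive": 1.5, "visual": 0.3})


class TestPredictCompensation:
    def test_product_of_weight_and_recall(self):
        mem = dataclasses.replace(default_memory(TRAIN), w_cw=0.627)
        assert predict_compensation(mem, TRAIN, "cw") == pytest.approx(0.627)
        visual_probe = dataclasses.replace(TRAIN, modality="visual")
        assert predict_compensation(mem, visual_probe, "cw") == pytest.approx(
            0.627 * 0.352, abs=1e-9
        )

    def test_zero_recall_annihilates(self):
        tuning = TuningParams(
            modality_gain={
                ("passive", "passive"): 1.0,
                ("passive", "visual"): 0.0,
                ("visual", "visual"): 1.0,
                ("visual", "passive"): 0.0,
            }
        )
        mem = dataclasses.replace(default_memory(TRAIN, tuning), w_cw=0.9)
        probe = dataclasses.replace(TRAIN, modality="visual")
        assert predict_compensation(mem, probe, "cw") == 0.0

    def test_unknown_context_rejected(self):
        mem = default_memory(TRAIN)
        with pytest.raises(ValueError):
            predict_compensation(mem, TRAIN, "sideways")


class TestUpdate:
    def test_no_drive_no_decay_is_identity(self):
        mem = MemoryState(
            w_cw=0.4, retention=1.0, learning_rate=0.1, trained={"cw": TRAIN}
        )
        out = update(mem, 0.0, "cw", TRAIN)
        assert out.w_cw == mem.w_cw

    def test_fixed_point_under_unit_drive(self):
        # w <- A w + B (1 - w) converges to B / (1 - A + B)
        mem = default_memory(TRAIN)
        for _ in range(3000):
            mem = update(mem, 1.0 - mem.w_cw, "cw", TRAIN)
        assert mem.w_cw == pytest.approx(0.1 / (1 - 0.99 + 0.1), abs=1e-6)

    def test_alternating_contexts_learn_without_interference(self):
        mem = default_memory(TRAIN)
        for i in range(100):
            ctx = "cw" if i % 2 == 0 else "ccw"
            mem = update(mem, 1.0 - mem.weight(ctx), ctx, TRAIN)
        assert mem.w_cw > 0.3 and mem.w_ccw > 0.3
        assert mem.w_cw == pytest.approx(mem.w_ccw)

    def test_credit_scales_with_recall(self):
        far_probe = KinematicCondition(0.10, 2.8, "passive")
        mem = default_memory(TRAIN)
        near = update(mem, 1.0, "cw", TRAIN)
        far = update(mem, 1.0, "cw", far_probe)
        assert near.w_cw > far.w_cw > 0.0

    def test_between_session_forgetting(self):
        mem = dataclasses.replace(default_memory(TRAIN), w_cw=0.6, w_ccw=0.6)
        decayed = mem.apply_forgetting(200)
        assert decayed.w_cw == pytest.approx(0.6 * 0.99**200)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MemoryState(retention=0.0)
        with pytest.raises(ValueError):
            MemoryState(learning_rate=1.0)


class TestGeneralizationAsymmetry:
    def test_passive_surface_range_exceeds_visual(self):
        """Narrower passive tuning implies a wider spread of recall over the
        probe grid than visual tuning (more pronounced generalization
        fall-off for passive lead-ins)."""
        tuning = TuningParams()
        ranges = {}
        for modality in ("passive", "visual"):
            trained = KinematicCondition(0.10, 0.70, modality)
            vals = [
                recall_weight(c, trained, tuning)
                for c in condition_grid(modality)
                if c.modality == modality
            ]
            ranges[modality] = max(vals) - min(vals)
        assert ranges["passive"] > ranges["visual"]
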