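"""Stimulus-schedule construction: mappings, task conditions, random walks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ebpb.config import default_config
from ebpb.connectome import eb, N_WEDGES
from ebpb.protocols import (azimuth_to_eb_region, cue_to_pb_targets,
                            make_condition, make_lesion, make_random_walk,
                            make_rotation_epoch, position_to_azimuth)


class TestAzimuthMapping:
    def test_cue_at_40_degrees_falls_in_R2(self):
        assert azimuth_to_eb_region(40.0).label == "R2"

    @settings(derandomize=True, max_examples=60)
    @given(a=st.floats(-720, 720, allow_nan=False))
    def test_periodicity(self, a):
        assert azimuth_to_eb_region(a) == azimuth_to_eb_region(a + 360.0)

    def test_receptive_arcs_partition_circle_equally(self):
        angles = np.arange(0.0, 360.0, 0.5)
        counts = {}
        for a in angles:
            counts[azimuth_to_eb_region(a).label] = \
                counts.get(azimuth_to_eb_region(a).label, 0) + 1
        assert len(counts) == 16
        assert set(counts.values()) == {45}  # 22.5 deg / 0.5 deg

    def test_center_roundtrip(self):
        for w in range(16):
            az = position_to_azimuth(w)
            assert azimuth_to_eb_region(az).position == w

    def test_infinite_angle_rejected(self):
        with pytest.raises(ValueError):
            azimuth_to_eb_region(float("inf"))


class TestCueMapping:
    def test_R2_maps_to_R5_L3(self):
        r, l = cue_to_pb_targets(eb("R2"))
        assert (r.label, l.label) == ("R5", "L3")

    def test_dual_partners_share_targets(self):
        assert cue_to_pb_targets(eb("R2")) == cue_to_pb_targets(eb("R3"))

    def test_all_pairs_bilateral(self):
        for w in ("R1", "R4", "R8", "L1", "L5", "L8"):
            r, l = cue_to_pb_targets(eb(w))
            assert r.label[0] == "R" and l.label[0] == "L"

    def test_rejects_pb_region(self):
        from ebpb.connectome import pb
        with pytest.raises(ValueError):
            cue_to_pb_targets(pb("R5"))


class TestConditions:
    def test_condition1_epochs(self, config):
        p = make_condition(1, 40.0, config, "c-ring")
        cues = [e for e in p.epochs if e.target[0] == "pb_region"]
        assert {e.target[1] for e in cues} == {"R5", "L3"}
        for e in cues:
            assert (e.t_start_ms, e.t_end_ms) == (0.0, 1000.0)
            assert e.rate_hz == 50.0 and e.g_max_ns == 2.1
        assert np.allclose(p.truth.azimuth_deg, 40.0)

    def test_condition1_two_cue_variant(self, config):
        p = make_condition(1, 40.0, config, "c-ring",
                           {"second_cue_deg": 200.0})
        cues = [e for e in p.epochs if e.target[0] == "pb_region"]
        assert len(cues) == 4
        rates = sorted({e.rate_hz for e in cues})
        assert rates == [0.6 * 50.0, 50.0]  # dim cue at configured fraction

    def test_condition2_advances_one_wedge_per_second(self, config):
        p = make_condition(2, 40.0, config, "c-ring",
                           {"move_ms": 4000.0, "phases": 1})
        az = p.truth
        # clockwise at 22.5 deg/s after the 1 s static cue
        assert az.at(np.array([1000.0]))[0] == pytest.approx(40.0)
        assert az.at(np.array([2000.0]))[0] == pytest.approx(40.0 - 22.5)
        cues = sorted((e.t_start_ms, e.t_end_ms, e.target[1])
                      for e in p.epochs if e.target[0] == "pb_region")
        # targets switch when the cue crosses a wedge boundary
        assert len({c[2] for c in cues}) > 2

    def test_condition2_reversal(self, config):
        p = make_condition(2, 40.0, config, "c-ring",
                           {"move_ms": 2000.0, "phases": 2})
        a0 = p.truth.at(np.array([1000.0]))[0]
        a1 = p.truth.at(np.array([3000.0]))[0]
        a2 = p.truth.at(np.array([5000.0]))[0]
        assert a1 == pytest.approx(a0 - 45.0)
        assert a2 == pytest.approx(a0)  # swept back

    def test_condition3_gating_and_truth_consistency(self, config):
        p = make_condition(3, 40.0, config, "full",
                           {"segments": [("forward", 1000.0),
                                         ("CCW", 2000.0)]})
        rot = [e for e in p.epochs if e.group == "rotation"]
        assert len(rot) == 1 and rot[0].target == ("pb_side", "R")
        # truth slope is -58.5 deg/s during the CCW rotation epoch
        t0, t1 = rot[0].t_start_ms, rot[0].t_end_ms
        slope = (p.truth.at(np.array([t1])) - p.truth.at(np.array([t0])))[0] \
            / ((t1 - t0) / 1000.0)
        assert slope == pytest.approx(-58.5)
        # R_PEN ceases 150 ms before rotation onset
        rpen = [e for e in p.epochs if e.target == ("class", "R_PEN")]
        assert any(e.t_end_ms == pytest.approx(t0 - 150.0) for e in rpen)
        # R_PEI ceases 150 ms before rotation offset
        rpei = [e for e in p.epochs if e.target == ("class", "R_PEI")]
        assert any(e.t_end_ms == pytest.approx(t1 - 150.0) for e in rpei)
        p.validate()

    def test_unknown_option_rejected(self, config):
        with pytest.raises(ValueError):
            make_condition(1, 40.0, config, "c-ring", {"bogus": 1})

    def test_unknown_circuit_rejected(self, config):
        with pytest.raises(ValueError):
            make_condition(1, 40.0, config, "d-ring")


class TestRotationEpoch:
    def test_ccw_targets_right_side(self, config):
        e = make_rotation_epoch("CCW", 0.0, 1000.0, config=config)
        assert e.target == ("pb_side", "R")
        assert e.rate_hz == 3150.0 and e.g_max_ns == 0.3
        assert e.pool_total  # quoted as total over the upstream group

    def test_cw_targets_left_side(self, config):
        assert make_rotation_epoch("CW", 0.0, 1000.0).target == ("pb_side", "L")

    def test_zero_rate_null_rotation(self):
        e = make_rotation_epoch("CW", 0.0, 500.0, rate_hz=0.0)
        assert e.rate_hz == 0.0

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            make_rotation_epoch("CW", 0.0, 0.0)


class TestRandomWalk:
    def test_deterministic_given_seed(self, config):
        p1 = make_random_walk(20.0, seed=42, config=config)
        p2 = make_random_walk(20.0, seed=42, config=config)
        assert [(e.target, e.t_start_ms, e.t_end_ms) for e in p1.epochs] == \
               [(e.target, e.t_start_ms, e.t_end_ms) for e in p2.epochs]
        assert np.array_equal(p1.truth.azimuth_deg, p2.truth.azimuth_deg)

    def test_segment_bounds_and_speed(self, config):
        p = make_random_walk(60.0, seed=7, config=config)
        rots = [e for e in p.epochs if e.group == "rotation"]
        assert rots, "walk contains rotations"
        for e in rots:
            dur_s = (e.t_end_ms - e.t_start_ms) / 1000.0
            angle = dur_s * 58.5
            assert 0.0 < angle <= 90.0 + 1e-6
            if dur_s < 0.3:
                continue  # too short to probe an interior slope
            # truth slope inside the epoch is +-58.5 deg/s
            tm = (e.t_start_ms + e.t_end_ms) / 2
            d = (p.truth.at(np.array([tm + 50])) - p.truth.at(np.array([tm - 50])))[0]
            assert abs(abs(d / 0.1) - 58.5) < 1e-6
        # forward (non-rotation) time: truth is flat (pad the rotation
        # bounds by one 10 ms grid step to skip boundary samples)
        t = p.truth.t_ms
        in_rot = np.zeros(len(t), bool)
        for e in rots:
            in_rot |= (t >= e.t_start_ms - 10.0) & (t <= e.t_end_ms + 10.0)
        flat = np.diff(p.truth.azimuth_deg)[~in_rot[:-1] & ~in_rot[1:]]
        assert np.allclose(flat, 0.0)

    def test_gating_exclusivity(self, config):
        p = make_random_walk(60.0, seed=3, config=config)
        p.validate()  # raises if R_PEI and R_PEN drives overlap

    def test_bad_duration(self, config):
        with pytest.raises(ValueError):
            make_random_walk(0.0, seed=1, config=config)


class TestLesion:
    def test_lesion_adds_hyperpolarizing_current(self, config):
        p = make_condition(1, 40.0, config, "full")
        q = make_lesion(p, "R_PEI", config)
        assert q.lesions == {"R_PEI": -0.5}
        assert p.lesions == {}  # original untouched

    def test_unknown_ring_rejected(self, config):
        p = make_condition(1, 40.0, config, "full")
        with pytest.raises(ValueError):
            make_lesion(p, "EIP", config)
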