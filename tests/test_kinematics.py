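"""Body-axis fitting, outlier removal, step segmentation and phase."""

import numpy as np
import pytest

import flysteer as fs
from flysteer.kinematics import (
    LEGS,
    compute_continuous_estimates,
    compute_leg_phase,
    compute_step_parameters,
    find_ap_extrema,
    segment_steps,
    step_direction_deg,
)


def _axis_session(points, mode="free", n=3):
    """Session with constant landmark positions (n frames)."""
    kp = {k: np.tile(np.asarray(v, float), (n, 1)) for k, v in points.items()}
    for leg in ("L1", "L2", "L3", "R1", "R2", "R3"):
        kp.setdefault(leg, np.zeros((n, 2)))
    return fs.TrackedSession(time=np.arange(n) * 0.01, keypoints=kp, mode=mode)


FREE_LANDMARKS = {
    "head": (1.0, 0.0),
    "postpronotal_left": (0.7, 0.1),
    "postpronotal_right": (0.7, -0.1),
    "scutellum": (0.5, 0.0),
    "abdomen": (0.0, 0.0),
}


class TestBodyAxis:
    def test_collinear_landmarks(self):
        s = _axis_session(FREE_LANDMARKS)
        frame = fs.fit_body_axis(s)
        assert frame.heading_deg[0] == pytest.approx(0.0, abs=1e-9)
        assert frame.body_length[0] == pytest.approx(1.0)
        np.testing.assert_allclose(frame.ap_axis[0], [1.0, 0.0], atol=1e-12)

    def test_rotation_equivariance(self):
        ang = np.radians(90.0)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = {k: tuple(R @ np.asarray(v)) for k, v in FREE_LANDMARKS.items()}
        frame = fs.fit_body_axis(_axis_session(rotated))
        assert frame.heading_deg[0] == pytest.approx(90.0)
        assert frame.body_length[0] == pytest.approx(1.0)

    def test_matches_closed_form_pca_under_jitter(self):
        rng = np.random.default_rng(0)
        pts = {
            "head": (1.0, 0.01),
            "postpronotal_left": (0.7, 0.12),
            "postpronotal_right": (0.7, -0.08),
            "scutellum": (0.5, -0.02),
            "abdomen": (0.0, 0.015),
        }
        s = _axis_session(pts)
        frame = fs.fit_body_axis(s)
        # oracle: eigenvector of the scatter of the 4 fitted points
        ppl = 0.5 * (np.asarray(pts["postpronotal_left"]) + np.asarray(pts["postpronotal_right"]))
        P = np.stack([pts["head"], ppl, pts["scutellum"], pts["abdomen"]])
        C = P - P.mean(axis=0)
        w, v = np.linalg.eigh(C.T @ C)
        major = v[:, np.argmax(w)]
        if major[0] < 0:
            major = -major
        np.testing.assert_allclose(frame.ap_axis[0], major, atol=1e-10)

    def test_degenerate_configuration_raises(self):
        pts = {k: (0.3, 0.2) for k in FREE_LANDMARKS}
        with pytest.raises(ValueError, match="degenerate"):
            fs.fit_body_axis(_axis_session(pts))


class TestBodyFrameProjection:
    def test_midpoint_and_head_positions(self):
        pts = dict(FREE_LANDMARKS)
        pts["L1"] = pts["scutellum"]          # at the midpoint
        pts["R1"] = pts["head"]               # at the head
        s = _axis_session(pts)
        frame = fs.fit_body_axis(s)
        body = fs.to_body_frame(s, frame, keys=["L1", "R1"])
        np.testing.assert_allclose(body["L1"][0], [0.0, 0.0], atol=1e-12)
        # head AP = +0.5 when the midpoint bisects head-abdomen
        assert body["R1"][0, 0] == pytest.approx(0.5)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        pts = dict(FREE_LANDMARKS)
        pts["L2"] = (0.45, 0.3)
        s = _axis_session(pts)
        body = fs.to_body_frame(s, fs.fit_body_axis(s), keys=["L2"])
        ang = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = rng.normal(size=2) * 10
        moved = {k: tuple(R @ np.asarray(v) + shift) for k, v in pts.items()}
        s2 = _axis_session(moved)
        body2 = fs.to_body_frame(s2, fs.fit_body_axis(s2), keys=["L2"])
        np.testing.assert_allclose(body2["L2"], body["L2"], atol=1e-10)


class TestOutlierRemoval:
    def test_clean_trace_unchanged(self):
        x = np.sin(np.linspace(0, 3, 600))
        np.testing.assert_array_equal(fs.remove_position_outliers(x), x)

    def test_single_spike_replaced_by_local_median(self):
        # brute-force application of the rule on a constructed trace
        x = np.linspace(0.0, 1.0, 600)
        x_spiked = x.copy()
        x_spiked[300] += 10.0
        out = fs.remove_position_outliers(x_spiked)
        med5 = np.median(x_spiked[298:303])
        assert out[300] == pytest.approx(med5)
        mask = np.ones(600, bool)
        mask[300] = False
        np.testing.assert_array_equal(out[mask], x_spiked[mask])

    def test_constant_trace_with_spike(self):
        x = np.full(600, 2.0)
        x[100] = 5.0
        out = fs.remove_position_outliers(x)
        assert np.allclose(out, 2.0)


class TestStepSegmentation:
    def test_constant_position_gives_no_steps(self):
        assert segment_steps(np.full(100, 0.3)) == []

    def test_sawtooth_matches_brute_force_extrema(self):
        # 10 cycles of an asymmetric sawtooth, 25 frames each
        cycle = np.concatenate([np.linspace(-0.1, 0.1, 11)[1:], np.linspace(0.1, -0.1, 16)[1:]])
        x = np.concatenate([np.full(5, -0.1), np.tile(cycle, 10)])
        t = np.arange(len(x)) * 0.004
        triplets = segment_steps(x, t)
        # brute-force oracle: sign changes of the difference series
        d = np.sign(np.diff(x))
        change = np.flatnonzero(d[1:] != d[:-1]) + 1
        mins = [i for i in change if d[i - 1] < 0]
        maxs = [i for i in change if d[i - 1] > 0]
        # every complete min-max-min cycle between brute-force minima is found
        assert len(triplets) == len(mins) - 1 == 8
        for (a, b, c) in triplets:
            assert a in mins and b in maxs and c in mins

    def test_single_cycle(self):
        x = np.concatenate([np.linspace(0.2, 0.0, 10), np.linspace(0.0, 0.2, 10)[1:],
                            np.linspace(0.2, 0.0, 10)[1:], np.linspace(0.0, 0.1, 5)[1:]])
        t = np.arange(len(x)) * 0.01
        triplets = segment_steps(x, t)
        assert len(triplets) == 1

    def test_jitter_below_excursion_threshold_ignored(self):
        rng = np.random.default_rng(1)
        x = np.full(200, 0.1) + rng.normal(0, 0.002, 200)
        assert segment_steps(x, np.arange(200) * 0.004) == []


class TestStepParameters:
    def _series(self):
        # one cycle: min at 0 (AP 0.10), max at 10 (AP 0.30), min at 20 (AP 0.10)
        ap = np.concatenate([np.linspace(0.10, 0.30, 11), np.linspace(0.30, 0.10, 11)[1:]])
        ml = np.full_like(ap, 0.1)
        t = np.arange(len(ap)) * 0.01
        return ap, ml, t

    def test_stride_length_is_ap_difference(self):
        ap, ml, t = self._series()
        st = compute_step_parameters((0, 10, 20), ap, ml, t, "R1", mode="tethered")
        assert st.stride_length == pytest.approx(0.20)
        assert st.aep == pytest.approx((0.30, 0.1))
        assert st.pep == pytest.approx((0.10, 0.1))

    def test_shorter_half_is_swing_in_tethered_mode(self):
        # halves of 30 ms and 70 ms
        ap = np.concatenate([np.linspace(0.1, 0.3, 4), np.linspace(0.3, 0.1, 8)[1:]])
        t = np.arange(len(ap)) * 0.01
        st = compute_step_parameters((0, 3, 10), ap, np.zeros_like(ap), t, "L2", mode="tethered")
        assert st.swing_half == "first"
        ap2 = ap[::-1] * 0 + np.concatenate([np.linspace(0.1, 0.3, 8), np.linspace(0.3, 0.1, 4)[1:]])
        st2 = compute_step_parameters((0, 7, 10), ap2, np.zeros_like(ap2), t, "L2", mode="tethered")
        assert st2.swing_half == "second"

    def test_faster_half_is_swing_in_free_mode(self):
        ap, ml, t = self._series()
        # world trajectory: fast first half, slow second half
        world = np.zeros((len(ap), 2))
        world[:11, 0] = np.linspace(0, 2.0, 11)
        world[11:, 0] = 2.0 + np.linspace(0, 0.2, 11)[1:]
        st = compute_step_parameters((0, 10, 20), ap, ml, t, "R1", mode="free", world_xy=world)
        assert st.swing_half == "first"

    def test_straight_backward_power_stroke_is_zero_degrees(self):
        assert step_direction_deg("R1", (0.3, 0.1), (0.1, 0.1)) == pytest.approx(0.0)
        assert step_direction_deg("L1", (0.3, -0.1), (0.1, -0.1)) == pytest.approx(0.0)

    def test_direction_positive_when_pep_moves_away_from_midline(self):
        # right leg, PEP displaced to the right (away from midline)
        assert step_direction_deg("R1", (0.3, 0.1), (0.1, 0.2)) > 0
        # mirrored left leg gives the same signed value
        assert step_direction_deg("L1", (0.3, -0.1), (0.1, -0.2)) == pytest.approx(
            step_direction_deg("R1", (0.3, 0.1), (0.1, 0.2))
        )

    def test_zero_duration_half_step_rejected(self):
        ap, ml, t = self._series()
        t2 = t.copy()
        t2[10] = t2[0]
        with pytest.raises(ValueError):
            compute_step_parameters((0, 10, 20), ap, ml, t2, "R1", mode="tethered")


class TestContinuousEstimates:
    def _gait(self, n_cycles=10, amp=None):
        # piecewise-linear gait, 20 frames/cycle, optional per-cycle amplitude
        amps = np.full(n_cycles, 0.2) if amp is None else amp
        ap = [np.full(3, -0.1)]
        for a in amps:
            ap.append(np.linspace(-a / 2, a / 2, 9)[1:])
            ap.append(np.linspace(a / 2, -a / 2, 13)[1:])
        x = np.concatenate(ap)
        t = np.arange(len(x)) * 0.005
        return x, t

    def test_constant_gait_gives_constant_stride(self):
        x, t = self._gait()
        idx, kinds = find_ap_extrema(x, t)
        cont = compute_continuous_estimates(x, np.zeros_like(x), t, idx, kinds, "R2")
        valid = cont.valid
        assert np.allclose(cont.stride_length[valid], 0.2, atol=1e-9)

    def test_ramping_amplitude_interpolates_through_knots(self):
        amps = np.linspace(0.1, 0.3, 10)
        x, t = self._gait(amp=amps)
        idx, kinds = find_ap_extrema(x, t)
        cont = compute_continuous_estimates(x, np.zeros_like(x), t, idx, kinds, "R2")
        # at each anterior extremum the continuous AEP equals the sample
        for i, k in zip(idx, kinds):
            if k == "max":
                assert cont.aep_ap[i] == pytest.approx(x[i], abs=1e-12)
            else:
                assert cont.pep_ap[i] == pytest.approx(x[i], abs=1e-12)

    def test_insufficient_extrema_flagged_invalid(self):
        x = np.linspace(0, 1, 50)
        cont = compute_continuous_estimates(x, x, np.arange(50.0), [10], ["max"], "L1")
        assert not cont.is_valid


class TestLegPhase:
    def _step(self):
        ap = np.concatenate([np.linspace(0.1, 0.3, 11), np.linspace(0.3, 0.1, 11)[1:]])
        t = np.arange(len(ap)) * 0.01
        st = compute_step_parameters((0, 10, 20), ap, np.zeros_like(ap), t, "R1", mode="tethered")
        return ap, [st]

    def test_anchor_values(self):
        ap, steps = self._step()
        phase = compute_leg_phase(ap, steps)
        assert phase[0] == pytest.approx(0.0)       # swing onset
        assert phase[10] == pytest.approx(180.0)    # swing/stance transition

    def test_ap_midpoints_map_to_90_and_270(self):
        ap, steps = self._step()
        phase = compute_leg_phase(ap, steps)
        assert phase[5] == pytest.approx(90.0)
        assert phase[15] == pytest.approx(270.0)

    def test_phase_monotone_within_half_steps(self):
        ap, steps = self._step()
        phase = compute_leg_phase(ap, steps)
        assert np.all(np.diff(phase[0:11]) > 0)
        assert np.all(np.diff(phase[10:20]) > 0)


def test_pipeline_matches_ground_truth(turning_session, turning_kinematics):
    """On noise-free synthetic gait, step counts and strides match ground truth."""
    _, steps, _ = turning_kinematics
    gt = turning_session.ground_truth["steps"]
    dt = 1.0 / turning_session.config.frame_rate_legs
    for leg in LEGS:
        assert len(steps[leg]) == len(gt[leg])
        for st, g in zip(steps[leg], gt[leg]):
            slope = abs(st.aep[0] - st.pep[0]) / (st.mid_time - st.start_time)
            assert abs(st.stride_length - g[3]) <= slope * dt
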