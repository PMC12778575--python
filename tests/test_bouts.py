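"""Turning-bout detection, canonicalization and step-delta extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import flysteer as fs
from flysteer._smoothing import gaussian_smooth
from flysteer.bouts import bout_triggered_stride, mirror_steps, select_bouts
from flysteer.kinematics import LEGS, step_table


def raised_cosine_trace(peak, crossing_sep, rate=250.0, total=6.0, center=3.0, boundary=10.0):
    """Rotational-velocity bump whose 10-deg/s crossings are crossing_sep apart."""
    r = boundary / peak
    phi = np.arccos(1 - 2 * r)
    D = crossing_sep / (1 - phi / np.pi)
    t = np.arange(0, total, 1 / rate)
    x = np.zeros_like(t)
    inside = np.abs(t - center) <= D / 2
    x[inside] = peak * 0.5 * (1 + np.cos(2 * np.pi * (t[inside] - center) / D))
    return t, x


class TestDetection:
    def test_zero_trace_gives_no_bouts(self):
        assert fs.detect_turning_bouts(np.zeros(2000), rate=250.0) == []

    def test_raised_cosine_boundaries_match_analytic_crossings(self):
        t, x = raised_cosine_trace(peak=100.0, crossing_sep=0.5)
        bouts = fs.detect_turning_bouts(x, rate=250.0)
        assert len(bouts) == 1
        b = bouts[0]
        assert b.duration == pytest.approx(0.5, abs=0.01)
        assert b.start_time == pytest.approx(3.0 - 0.25, abs=0.005)
        assert b.end_time == pytest.approx(3.0 + 0.25, abs=0.005)
        assert b.peak_rot_velocity == pytest.approx(100.0, rel=0.01)
        assert b.direction_original == "right"

    def test_duration_filter_rejects_wide_bouts(self):
        t, x = raised_cosine_trace(peak=100.0, crossing_sep=0.9)
        assert fs.detect_turning_bouts(x, rate=250.0) == []

    def test_duration_filter_rejects_narrow_bouts(self):
        t, x = raised_cosine_trace(peak=100.0, crossing_sep=0.2)
        assert fs.detect_turning_bouts(x, rate=250.0) == []

    def test_left_turns_found_in_negated_trace(self):
        t, x = raised_cosine_trace(peak=80.0, crossing_sep=0.4)
        bouts = fs.detect_turning_bouts(-x, rate=250.0)
        assert len(bouts) == 1
        assert bouts[0].direction_original == "left"
        assert bouts[0].peak_rot_velocity == pytest.approx(-80.0, rel=0.01)

    def test_short_trace_returns_empty(self):
        assert fs.detect_turning_bouts(np.full(50, 50.0), rate=250.0) == []


class TestClassification:
    def _bout(self, delta):
        return fs.TurningBout(
            peak_time=1.0, start_time=0.8, end_time=1.3, peak_rot_velocity=80.0,
            direction_original="right", forward_at_start=12.0, forward_at_peak=12.0 + delta,
        )

    def test_forward_drop_is_pivot(self):
        assert fs.classify_pivot_swerve(self._bout(-2.0)) == "pivot"

    def test_forward_rise_is_swerve(self):
        assert fs.classify_pivot_swerve(self._bout(+2.0)) == "swerve"

    def test_dead_zone_is_neither(self):
        assert fs.classify_pivot_swerve(self._bout(0.0)) == "neither"
        assert fs.classify_pivot_swerve(self._bout(-1.0)) == "neither"
        assert fs.classify_pivot_swerve(self._bout(+1.0)) == "neither"


class TestCanonicalization:
    def _steps(self):
        return pd.DataFrame(
            {
                "leg": ["L1", "R1"],
                "start_time": [0.0, 0.0],
                "end_time": [0.1, 0.1],
                "stride_length": [0.25, 0.15],
                "step_direction_deg": [10.0, -5.0],
                "aep_ap": [0.3, 0.3],
                "aep_ml": [-0.25, 0.25],
                "pep_ap": [0.05, 0.15],
                "pep_ml": [-0.25, 0.25],
            }
        )

    def test_right_turn_unchanged(self):
        b = fs.TurningBout(1.0, 0.8, 1.3, 80.0, "right")
        out, steps_by = fs.canonicalize_left_turns([b], self._steps())
        assert out[0].peak_rot_velocity == 80.0
        pd.testing.assert_frame_equal(steps_by[0], self._steps())

    def test_mirror_is_involution(self):
        steps = self._steps()
        pd.testing.assert_frame_equal(
            mirror_steps(mirror_steps(steps)).sort_index(), steps.sort_index()
        )

    def test_left_bout_mirrored(self):
        b = fs.TurningBout(1.0, 0.8, 1.3, -80.0, "left")
        out, steps_by = fs.canonicalize_left_turns([b], self._steps())
        assert out[0].peak_rot_velocity == 80.0
        mirrored = steps_by[0]
        # the short-stride leg was R1; after mirroring it carries the L1 label
        assert set(mirrored["leg"]) == {"L1", "R1"}
        assert mirrored.loc[mirrored["leg"] == "L1", "stride_length"].item() == 0.15

    def test_generator_left_bout_inside_legs_after_canonicalization(self):
        sched = (fs.CommandedBout(onset=3.0, duration=0.5, direction="left", magnitude=100.0),)
        s = fs.simulate_walking(fs.SimulationConfig(duration=8.0, seed=3, turn_schedule=sched))
        v = s.velocities_true
        bouts = fs.detect_turning_bouts(v.rotational_heavy, v.rate, forward=v.forward)
        assert len(bouts) == 1 and bouts[0].direction_original == "left"
        _, steps, _ = fs.leg_analysis(s.tracked)
        table = step_table(steps)
        canon, steps_by = fs.canonicalize_left_turns(bouts, table)
        mirrored = steps_by[0]
        b = canon[0]
        at_peak = mirrored[(mirrored["start_time"] <= b.peak_time) & (b.peak_time < mirrored["end_time"])]
        short = at_peak.set_index("leg")["stride_length"]
        # the generator shortened the (original) left legs; after the swap the
        # shortened legs carry R labels = inside of the canonical right turn
        assert short[["R1", "R2", "R3"]].mean() < short[["L1", "L2", "L3"]].mean()


class TestStepDeltas:
    def test_commanded_attenuation_recovered(self, turning_session, turning_kinematics):
        s = turning_session
        _, steps, _ = turning_kinematics
        table = step_table(steps)
        v = s.velocities_true
        bouts = fs.detect_turning_bouts(v.rotational_heavy, v.rate, forward=v.forward)
        bouts = select_bouts(bouts, peak_window=(90.0, 110.0))
        assert len(bouts) == 1
        canon, steps_by = fs.canonicalize_left_turns(bouts, table)
        ref = fs.not_turning_reference(table, v.time, v.rotational)
        deltas = fs.step_deltas_at_peak(canon[0], steps_by[0], ref)
        cfg = s.config
        kappa_pk = 100.0 / (cfg.rot_gain * (cfg.gesture_gain_inside + cfg.gesture_gain_outside))
        expected_inside = -cfg.gesture_gain_inside * kappa_pk * cfg.base_stride_length
        expected_outside = cfg.gesture_gain_outside * kappa_pk * cfg.base_stride_length
        # step extrema sample the command envelope up to half a stride away
        # from the peak, so realized deltas fall slightly short of the
        # analytic peak value
        for leg in ("R1", "R2", "R3"):
            assert deltas.d_stride_length[leg] == pytest.approx(expected_inside, rel=0.15)
        for leg in ("L1", "L2", "L3"):
            assert deltas.d_stride_length[leg] == pytest.approx(expected_outside, rel=0.15)

    def test_quiet_session_reference_equals_global_mean(self, quiet_session):
        s = quiet_session
        _, steps, _ = fs.leg_analysis(s.tracked)
        table = step_table(steps)
        v = s.velocities_true
        ref = fs.not_turning_reference(table, v.time, v.rotational)
        for leg, grp in table.groupby("leg"):
            assert ref[leg]["stride_length"] == pytest.approx(grp["stride_length"].mean())

    def test_missing_covering_step_flagged(self):
        b = fs.TurningBout(1.0, 0.8, 1.3, 80.0, "right", canonical=True)
        steps = pd.DataFrame(
            {
                "leg": ["L1"], "start_time": [2.0], "end_time": [2.1],
                "stride_length": [0.2], "step_direction_deg": [0.0],
                "aep_ap": [0.3], "aep_ml": [0.2], "pep_ap": [0.1], "pep_ml": [0.2],
            }
        )
        deltas = fs.step_deltas_at_peak(b, steps, {"L1": {
            "stride_length": 0.2, "step_direction_deg": 0.0,
            "aep_ap": 0.3, "aep_ml": 0.2, "pep_ap": 0.1, "pep_ml": 0.2}})
        assert set(deltas.missing_legs) == set(LEGS)


class TestBoutTriggeredStride:
    def _bout_at(self, t):
        return fs.TurningBout(t, t - 0.2, t + 0.2, 100.0, "right")

    def test_triangular_bump_fwhm(self):
        # triangle of half-height width 0.25 s around each bout peak
        t = np.arange(0, 20, 0.004)
        stride = np.full_like(t, 0.1)
        peaks = [5.0, 10.0, 15.0]
        for p in peaks:
            tri = np.clip(1 - np.abs(t - p) / 0.25, 0, None)
            stride = stride + 0.1 * tri
        out = bout_triggered_stride([self._bout_at(p) for p in peaks], t, {"L1": stride})
        np.testing.assert_allclose(out["fwhm"]["L1"], 0.25, atol=0.02)
        mean = out["mean"]["L1"]
        assert mean.min() == pytest.approx(0.0, abs=1e-12)
        assert mean.max() == pytest.approx(1.0, abs=1e-12)

    def test_zero_range_snippets_skipped(self):
        t = np.arange(0, 10, 0.01)
        out = bout_triggered_stride([self._bout_at(5.0)], t, {"L1": np.full_like(t, 0.2)})
        assert out["skipped"]["L1"] == 1
        assert len(out["fwhm"]["L1"]) == 0

    def test_snippet_outside_trace_skipped(self):
        t = np.arange(0, 2, 0.01)
        out = bout_triggered_stride([self._bout_at(0.2)], t, {"L1": np.sin(t)})
        assert out["skipped"]["L1"] == 1


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_canonicalization_is_involution(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(2, 12)
    steps = pd.DataFrame(
        {
            "leg": rng.choice(LEGS, n),
            "start_time": np.sort(rng.uniform(0, 10, n)),
            "end_time": np.sort(rng.uniform(0, 10, n)) + 0.1,
            "stride_length": rng.uniform(0.1, 0.3, n),
            "step_direction_deg": rng.uniform(-180, 180, n),
            "aep_ap": rng.normal(size=n),
            "aep_ml": rng.normal(size=n),
            "pep_ap": rng.normal(size=n),
            "pep_ml": rng.normal(size=n),
        }
    )
    pd.testing.assert_frame_equal(mirror_steps(mirror_steps(steps)), steps)


def test_detected_bouts_disjoint_and_filtered(turning_session):
    v = turning_session.velocities_true
    bouts = fs.detect_turning_bouts(v.rotational_heavy, v.rate)
    for b in bouts:
        assert 0.3 <= b.duration <= 0.7
    for a, b in zip(bouts, bouts[1:]):
        assert a.end_time <= b.start_time
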