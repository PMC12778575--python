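"""Tuning curves, conditioned rates, common phase and spike-phase profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flysteer as fs


class TestBinnedTuning:
    def test_identity_relationship(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 5000)
        curve = fs.binned_tuning(x, x.copy(), rate=100.0, n_bins=20, min_count=10, lag_offset=0.0)
        assert curve.pearson_r == pytest.approx(1.0)
        good = np.isfinite(curve.bin_means)
        np.testing.assert_allclose(curve.bin_means[good], curve.bin_centers[good], atol=0.06)

    def test_independent_series_have_near_zero_r(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        curve = fs.binned_tuning(x, y, rate=100.0, lag_offset=0.0)
        assert abs(curve.pearson_r) < 0.05

    def test_lag_offset_pairs_with_earlier_neural_samples(self):
        # behavior x is a delayed copy of the neural series y: pairing x(t)
        # with y(t - lag) restores r = 1
        rng = np.random.default_rng(2)
        y = rng.normal(size=2000)
        x = np.roll(y, 10)  # x(t) = y(t - 10 samples)
        curve = fs.binned_tuning(x, y, rate=100.0, lag_offset=0.1, min_count=5)
        assert curve.pearson_r > 0.999

    def test_sparse_bins_excluded(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.uniform(0, 1, 980), np.full(20, 5.0)])
        y = x.copy()
        curve = fs.binned_tuning(x, y, rate=100.0, n_bins=10, min_count=50, lag_offset=0.0)
        assert np.isnan(curve.bin_means[-1])
        assert curve.bin_counts[-1] == 20

    def test_generator_coupling_recovered(self, turning_session):
        s = turning_session
        rot = s.velocities_true.rotational
        rate = s.rate_true.rate
        curve = fs.binned_tuning(rot, rate, rate=250.0, n_bins=20, min_count=20, lag_offset=0.1)
        assert curve.pearson_r > 0.8
        good = np.isfinite(curve.bin_means)
        assert np.all(np.diff(curve.bin_means[good]) > -1e-9)


class TestSplitByTurning:
    def test_all_straight_walking_leaves_turning_empty(self):
        x = np.random.default_rng(0).normal(size=1000)
        turning, not_turning = fs.split_by_turning(
            x, x.copy(), 100.0, np.zeros(1000), lag_offset=0.0, min_count=5
        )
        assert turning.empty and not not_turning.empty

    def test_threshold_sample_goes_to_turning(self):
        x = np.arange(100.0)
        rot = np.full(100, 25.0)  # exactly at threshold -> turning (>= rule)
        turning, not_turning = fs.split_by_turning(
            x, x.copy(), 100.0, rot, lag_offset=0.0, min_count=1
        )
        assert not_turning.empty and turning.n_samples == 100


class TestConditionedRate:
    def test_constant_forward_velocity_leaves_conditions_empty(self):
        n = 1000
        out = fs.conditioned_rate(
            np.ones(n), np.full(n, 75.0), np.zeros(n), rate=250.0
        )
        assert out["n_decelerating"] == 0 and out["n_accelerating"] == 0
        assert np.isnan(out["mean_decelerating"])

    def test_constant_rate_gives_zero_difference(self):
        n = 1000
        accel = np.concatenate([np.full(n // 2, -20.0), np.full(n // 2, 20.0)])
        out = fs.conditioned_rate(np.full(n, 3.0), np.full(n, 75.0), accel, rate=250.0)
        assert out["mean_decelerating"] == pytest.approx(3.0)
        assert out["difference"] == pytest.approx(0.0)

    def test_rate_boost_during_deceleration_detected(self):
        n = 2000
        accel = np.concatenate([np.full(n // 2, -20.0), np.full(n // 2, 20.0)])
        rate = np.where(accel < 0, 2.0, 1.0)
        out = fs.conditioned_rate(rate, np.full(n, 75.0), accel, rate=250.0)
        assert out["difference"] > 0.9


class TestCommonPhase:
    def test_identical_phases_pass_through(self):
        ph = np.linspace(0, 720, 500) % 360
        out, excl = fs.common_stride_phase({"L1": ph, "R2": ph}, "R2")
        np.testing.assert_allclose(out, ph, atol=1e-9)
        assert excl == []

    def test_perfect_tripod_collapses_after_alignment(self):
        ph = np.linspace(0, 3600, 2000) % 360
        anti = (ph + 180.0) % 360
        phases = {"L1": ph, "R2": ph, "L3": ph, "R1": anti, "L2": anti, "R3": anti}
        out, excl = fs.common_stride_phase(phases, "R2")
        np.testing.assert_allclose(out, ph, atol=1e-6)

    def test_reference_change_shifts_by_constant_offset(self):
        ph = np.linspace(0, 3600, 2000) % 360
        phases = {"R2": ph, "R1": (ph + 180.0) % 360}
        a, _ = fs.common_stride_phase(phases, "R2")
        b, _ = fs.common_stride_phase(phases, "R1")
        d = (a - b + 180.0) % 360.0 - 180.0
        circ_dev = (d - d[0] + 180.0) % 360.0 - 180.0
        np.testing.assert_allclose(circ_dev, 0.0, atol=1e-6)

    def test_leg_without_phase_excluded(self):
        ph = np.linspace(0, 720, 500) % 360
        out, excl = fs.common_stride_phase({"R2": ph, "L1": np.full(500, np.nan)}, "R2")
        assert excl == ["L1"]
        np.testing.assert_allclose(out, ph, atol=1e-9)


class TestSpikePhaseProfile:
    def _phase(self, n=120_000, rate=1000.0, f=10.0):
        t = np.arange(n) / rate
        return t, (360.0 * f * t) % 360.0

    def test_uniform_spikes_give_flat_profile(self):
        t, ph = self._phase()
        rate = fs.RateTrace(times=t, rate=np.full_like(t, 25.0))
        spk = fs.simulate_spike_train(rate, seed=0)
        prof = fs.spike_phase_profile(spk.spike_times, ph, t, np.ones_like(t, bool), offset=0.1)
        depth, _ = fs.phase_modulation_depth(prof)
        assert depth < 3.0

    def test_spikes_at_single_phase_concentrate_in_one_bin(self):
        t, ph = self._phase()
        # spikes placed 100 ms after frames whose phase is 90 deg
        frames = np.flatnonzero(np.isclose(ph, 90.0, atol=2.0))[::5]
        spikes = t[frames] + 0.1
        spikes = spikes[spikes < t[-1]]
        prof = fs.spike_phase_profile(spikes, ph, t, np.ones_like(t, bool), offset=0.1)
        imax = np.nanargmax(prof.rate_modulation)
        assert prof.bin_centers[imax] == pytest.approx(90.0, abs=5.0)
        # occupancy-weighted mean of the modulation vanishes
        good = np.isfinite(prof.rate_modulation)
        assert np.sum(prof.rate_modulation[good] * prof.occupancy[good]) == pytest.approx(0.0, abs=1e-6)

    def test_circular_shift_invariance(self):
        t, ph = self._phase(n=60_000)
        rate = fs.phase_locked_rate(ph, t, baseline=20.0, depth=10.0, preferred_deg=120.0)
        spk = fs.simulate_spike_train(rate, seed=1)
        walking = np.ones_like(t, bool)
        p1 = fs.spike_phase_profile(spk.spike_times, ph, t, walking)
        p2 = fs.spike_phase_profile(spk.spike_times, ph + 360.0, t, walking)
        np.testing.assert_allclose(p1.rate_modulation, p2.rate_modulation, equal_nan=True)

    def test_locked_rate_recovered(self):
        t, ph = self._phase()
        rate = fs.phase_locked_rate(ph, t, baseline=25.0, depth=12.0, preferred_deg=200.0, offset=0.1)
        spk = fs.simulate_spike_train(rate, seed=2)
        prof = fs.spike_phase_profile(spk.spike_times, ph, t, np.ones_like(t, bool), offset=0.1)
        depth, pref = fs.phase_modulation_depth(prof)
        assert pref == pytest.approx(200.0, abs=5.0)
        assert depth == pytest.approx(12.0, rel=0.25)


class TestForwardSteppingMask:
    def test_straight_walking_fully_included(self, turning_kinematics):
        _, _, cont = turning_kinematics
        mask = fs.forward_stepping_mask(cont)
        # the synthetic gait steps straight backward; nearly all valid frames pass
        valid = np.logical_and.reduce([cont[l].valid for l in ("L2", "L3", "R2", "R3")])
        assert mask[valid].mean() > 0.99


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_profile_occupancy_weighted_mean_is_zero(seed):
    """Mean-removal identity holds for arbitrary spike/phase configurations."""
    rng = np.random.default_rng(seed)
    n = 2000
    t = np.arange(n) / 250.0
    ph = rng.uniform(0, 360, n)
    walking = rng.uniform(size=n) < 0.8
    spikes = np.sort(rng.uniform(0.2, t[-1], rng.integers(10, 300)))
    prof = fs.spike_phase_profile(spikes, ph, t, walking, offset=0.1, n_bins=36)
    good = np.isfinite(prof.rate_modulation)
    if good.any() and prof.n_spikes > 0:
        total = np.sum(prof.rate_modulation[good] * prof.occupancy[good])
        assert abs(total) < 1e-8 * max(1.0, prof.n_spikes)
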