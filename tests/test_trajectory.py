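import math

import numpy as np
import pytest

from tpmbend.exceptions import DomainError
from tpmbend.synthetic import OUParams, gen_trajectory
from tpmbend.trajectory import (
    Trajectory,
    amplitude_of_motion,
    asymmetry_factor,
    estimate_anchor_and_drift,
    estimate_tau,
    summarize,
)


def make_traj(x, y, frame_rate=25.0, exposure=0.0):
    t = np.arange(len(x)) / frame_rate
    return Trajectory(times=t, x=np.asarray(x, float), y=np.asarray(y, float),
                      frame_rate=frame_rate, exposure=exposure)


class TestAnchorAndDrift:
    def test_constant_position(self):
        traj = make_traj(np.full(1000, 7.0), np.full(1000, -3.0))
        corrected, anchor = estimate_anchor_and_drift(traj)
        assert anchor == pytest.approx([7.0, -3.0])
        assert np.allclose(corrected.x, 0.0)
        assert np.allclose(corrected.y, 0.0)

    def test_linear_drift_removed(self):
        t = np.arange(2000) / 25.0
        traj = Trajectory(times=t, x=3.0 * t, y=-1.5 * t, frame_rate=25.0)
        corrected, _ = estimate_anchor_and_drift(traj)
        interior = slice(100, -100)
        assert np.allclose(corrected.x[interior], 0.0, atol=1e-9)
        assert np.allclose(corrected.y[interior], 0.0, atol=1e-9)

    def test_ou_anchor_recovery(self):
        params = OUParams(tau=20.0, stationary_std=100.0, duration=300.0,
                          anchor=(120.0, -80.0), seed=3)
        traj = gen_trajectory(params)
        _, anchor = estimate_anchor_and_drift(traj)
        n_eff = len(traj) * (1000.0 / traj.frame_rate) / (2 * params.tau)
        bound = 3 * params.stationary_std / math.sqrt(n_eff)
        assert abs(anchor[0] - 120.0) < bound
        assert abs(anchor[1] + 80.0) < bound

    def test_too_short(self):
        traj = make_traj(np.zeros(50), np.zeros(50))
        with pytest.raises(DomainError):
            estimate_anchor_and_drift(traj, window=5.0)


class TestAmplitude:
    def test_isotropic_gaussian(self):
        rng = np.random.default_rng(5)
        sigma = 80.0
        traj = make_traj(rng.normal(0, sigma, 20000), rng.normal(0, sigma, 20000))
        amp = amplitude_of_motion(traj)
        assert amp == pytest.approx(sigma * math.sqrt(2), rel=0.02)

    def test_constant_is_zero(self):
        traj = make_traj(np.zeros(500), np.zeros(500))
        assert amplitude_of_motion(traj) == 0.0

    def test_ou_recovery(self):
        params = OUParams(tau=20.0, stationary_std=100.0, duration=300.0,
                          exposure=0.0, n_substeps=1, seed=8)
        traj = gen_trajectory(params)
        corrected, _ = estimate_anchor_and_drift(traj)
        amp = amplitude_of_motion(corrected)
        assert amp == pytest.approx(100.0 * math.sqrt(2), rel=0.02)

    def test_empty_error(self):
        traj = Trajectory(times=np.array([]), x=np.array([]), y=np.array([]))
        with pytest.raises(DomainError):
            amplitude_of_motion(traj)


class TestTau:
    def test_ou_recovery_within_15_percent(self):
        params = OUParams(tau=20.0, stationary_std=100.0, duration=300.0, seed=9)
        traj = gen_trajectory(params)
        corrected, _ = estimate_anchor_and_drift(traj)
        est = estimate_tau(corrected)
        assert est.valid
        assert est.tau_ms == pytest.approx(20.0, rel=0.15)

    def test_white_noise_flagged(self):
        rng = np.random.default_rng(10)
        traj = make_traj(rng.normal(0, 50, 3000), rng.normal(0, 50, 3000))
        est = estimate_tau(traj)
        assert est.tau_ms < 1000.0 / traj.frame_rate  # below one frame
        # either flagged invalid or fitted to a negligible value
        assert (not est.valid) or est.tau_ms < 5.0

    def test_axes_agree(self):
        params = OUParams(tau=20.0, stationary_std=100.0, duration=600.0, seed=11)
        traj = gen_trajectory(params)
        est = estimate_tau(traj)
        assert est.per_axis[0] == pytest.approx(est.per_axis[1], rel=0.3)

    def test_needs_enough_frames(self):
        traj = make_traj(np.random.default_rng(0).normal(0, 1, 100), np.zeros(100))
        with pytest.raises(DomainError):
            estimate_tau(traj)


class TestAsymmetry:
    def test_isotropic(self):
        rng = np.random.default_rng(12)
        traj = make_traj(rng.normal(0, 60, 20000), rng.normal(0, 60, 20000))
        assert asymmetry_factor(traj) == pytest.approx(1.0, abs=0.03)

    def test_one_dimensional_flagged(self):
        rng = np.random.default_rng(13)
        traj = make_traj(rng.normal(0, 60, 2000), rng.normal(0, 1e-3, 2000))
        assert asymmetry_factor(traj) > 10.0

    def test_two_to_one(self):
        rng = np.random.default_rng(14)
        traj = make_traj(rng.normal(0, 100, 50000), rng.normal(0, 50, 50000))
        assert asymmetry_factor(traj) == pytest.approx(2.0, rel=0.05)

    def test_degenerate(self):
        traj = make_traj(np.zeros(200), np.zeros(200))
        with pytest.raises(DomainError):
            asymmetry_factor(traj)


class TestSummarize:
    def test_blurred_ou_end_to_end(self):
        params = OUParams(tau=20.0, stationary_std=100.0, duration=300.0, seed=15)
        traj = gen_trajectory(params)
        s = summarize(traj)
        true_amp = 100.0 * math.sqrt(2)
        assert s.amplitude_raw < true_amp
        assert s.amplitude == pytest.approx(true_amp, rel=0.03)
        assert s.valid

    def test_unblurred_input(self):
        params = OUParams(tau=20.0, stationary_std=100.0, duration=300.0,
                          exposure=0.0, n_substeps=1, seed=16)
        traj = gen_trajectory(params)
        s = summarize(traj)
        assert s.amplitude == pytest.approx(s.amplitude_raw, rel=1e-9)

    def test_stuck_bead(self):
        rng = np.random.default_rng(17)
        traj = make_traj(5.0 + rng.normal(0, 0.5, 5000), -2.0 + rng.normal(0, 0.5, 5000))
        s = summarize(traj, min_amplitude=10.0)
        assert s.amplitude < 2.0
        assert not s.valid  # minimum-amplitude filter

    def test_failure_recorded_not_raised(self):
        traj = make_traj(np.zeros(40), np.zeros(40))  # too short
        s = summarize(traj)
        assert not s.valid
        assert "DomainError" in s.error


class TestPipelineRecovery:
    def test_median_relative_error_below_2_percent(self):
        rng = np.random.default_rng(99)
        errors = []
        for _ in range(50):
            std = rng.uniform(80.0, 180.0) / math.sqrt(2)
            params = OUParams(tau=rng.uniform(15.0, 30.0), stationary_std=std,
                              duration=300.0, seed=int(rng.integers(1 << 31)),
                              drift_velocity=(rng.uniform(-2, 2), rng.uniform(-2, 2)))
            s = summarize(gen_trajectory(params))
            errors.append(abs(s.amplitude / (std * math.sqrt(2)) - 1.0))
        assert np.median(errors) < 0.02
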