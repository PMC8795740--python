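import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hippocan.stripe import (
    PatternFormationError,
    PhaseTracker,
    StripeDynamicsFFT,
    StripePlate,
    UndefinedPhaseError,
    build_weight_matrix,
    calibrate_displacement_gain,
    estimate_phase,
    forward_input,
    most_unstable_period,
    relax_to_pattern,
    step_dynamics,
    step_rates,
)
from hippocan.trajectory import Arena, TrajectorySeries, generate_random_walk


class TestWeights:
    def test_kernel_zero_at_origin(self):
        # W0(0) = e^0 - e^0 = 0: a cell exactly at another's offset center
        # receives no inhibition from it
        W = build_weight_matrix(120, 20.0, 0.0, 1.0)
        assert np.allclose(np.diag(W), 0.0)

    def test_all_entries_inhibitory(self):
        W = build_weight_matrix(120, 20.0, 1.0, 10.0)
        assert W.max() <= 0.0

    def test_kernel_minimum_matches_brute_force_scan(self):
        """Analytic trough x* = sqrt(ln(g/b)/(g-b)) vs dense numeric scan."""
        lam = 20.0
        beta = 3.0 / lam**2
        gamma = 1.035 * beta
        x = np.linspace(1e-4, 3 * lam, 200001)
        w0 = np.exp(-gamma * x**2) - np.exp(-beta * x**2)
        x_scan = x[np.argmin(w0)]
        x_star = np.sqrt(np.log(gamma / beta) / (gamma - beta))
        assert x_star == pytest.approx(x_scan, abs=x[1] - x[0])

    def test_preconditions(self):
        with pytest.raises(ValueError):
            build_weight_matrix(120, 0.0, 1.0)
        with pytest.raises(ValueError):
            build_weight_matrix(30, 20.0, 1.0)  # fewer than 3 wavelengths

    def test_fft_dynamics_match_dense(self, rng):
        plate = StripePlate()
        dyn = StripeDynamicsFFT(120, 20.0, 1.0, 10.0, plate.tau)
        S = rng.uniform(0, 1, (5, 120))
        B = 1.0 + 0.1 * rng.standard_normal((5, 120))
        dense = step_rates(plate.weights, S, B, 0.001, plate.tau)
        fast = dyn.step(S, B, 0.001)
        assert np.allclose(dense, fast, atol=1e-12)


class TestDynamics:
    def test_forward_input_zero_velocity_uniform(self, formed_plate):
        assert np.allclose(forward_input(formed_plate, np.zeros(2)), 1.0)

    def test_forward_input_orthogonal_velocity_uniform(self, formed_plate):
        v = 0.4 * np.array([np.cos(formed_plate.theta + np.pi / 2),
                            np.sin(formed_plate.theta + np.pi / 2)])
        assert np.allclose(forward_input(formed_plate, v), 1.0)

    def test_forward_input_sign_alternation(self, formed_plate):
        v = 0.3 * formed_plate.direction
        B = forward_input(formed_plate, v)
        assert np.allclose(B[::2], 1.0 + formed_plate.alpha * 0.3)
        assert np.allclose(B[1::2], 1.0 - formed_plate.alpha * 0.3)

    def test_rates_stay_nonnegative(self, formed_plate, rng):
        plate = formed_plate.copy()
        for _ in range(50):
            step_dynamics(plate, rng.uniform(-0.5, 0.5, 2), 0.001)
            assert plate.rates.min() >= 0.0

    def test_unstable_dt_rejected(self, formed_plate):
        with pytest.raises(ValueError, match="dt"):
            step_dynamics(formed_plate.copy(), np.zeros(2), 0.1)

    @pytest.mark.parametrize("zeroed", ["k", "alpha"])
    def test_static_fringes_without_velocity_coupling(self, zeroed):
        """k = 0 or alpha = 0 leaves the stripes stationary under drive."""
        kwargs = dict(k=0.0) if zeroed == "k" else dict(alpha=0.0)
        plate = StripePlate(**kwargs)
        relax_to_pattern(plate, seed=1)
        for _ in range(2000):  # finish settling before measuring drift
            step_dynamics(plate, np.zeros(2), 0.001)
        v = 0.4 * plate.direction
        # applying the drive deforms the profile slightly (a one-time phase
        # offset); drift is the continuing motion after that transient
        for _ in range(2000):
            step_dynamics(plate, v, 0.001)
        p0 = estimate_phase(plate)
        for _ in range(5000):  # 5 s
            step_dynamics(plate, v, 0.001)
        per = plate.pattern_period
        drift = abs((estimate_phase(plate) - p0 + per / 2) % per - per / 2)
        assert drift / 5.0 < 0.01  # cells per second

    def test_zero_velocity_phase_stationary(self, formed_plate):
        plate = formed_plate.copy()
        tracker = PhaseTracker(plate.pattern_period, estimate_phase(plate))
        for _ in range(10000):  # 10 s
            step_dynamics(plate, np.zeros(2), 0.001)
        tracker.update(estimate_phase(plate))
        assert abs(tracker.cumulative) / 10.0 < 0.01

    def test_constant_velocity_gives_linear_phase_flow(self, formed_plate):
        plate = formed_plate.copy()
        v = 0.3 * plate.direction
        tracker = PhaseTracker(plate.pattern_period, estimate_phase(plate))
        track, times = [], []
        for i in range(4000):
            step_dynamics(plate, v, 0.001)
            if i % 10 == 0:
                track.append(tracker.update(estimate_phase(plate)))
                times.append(i * 0.001)
        fit = stats.linregress(times[50:], track[50:])
        assert fit.rvalue**2 > 0.999

    def test_orthogonal_motion_produces_no_drift(self, formed_plate):
        plate = formed_plate.copy()
        v = 0.4 * np.array([-np.sin(plate.theta), np.cos(plate.theta)])
        tracker = PhaseTracker(plate.pattern_period, estimate_phase(plate))
        for _ in range(4000):
            step_dynamics(plate, v, 0.001)
        tracker.update(estimate_phase(plate))
        assert abs(tracker.cumulative) < 0.1  # cells over 4 s


class TestFormation:
    def test_forms_within_half_second(self):
        plate = StripePlate()
        t = relax_to_pattern(plate, seed=3)
        assert t <= 0.5
        assert plate.rates.min() >= 0

    def test_profile_stable_between_450_and_500_ms(self):
        plate = StripePlate()
        plate.seed_noise(0.01, seed=4)
        B = forward_input(plate, 0.0)
        snap = {}
        for i in range(1, 501):
            plate.rates = step_rates(plate.weights, plate.rates, B, 0.001, plate.tau)
            if i in (450, 500):
                snap[i] = plate.rates.copy()
        r = np.corrcoef(snap[450], snap[500])[0, 1]
        assert r > 0.99

    def test_zero_init_develops_activity(self):
        plate = StripePlate()  # rates start at zero; B = 1 drives them up
        for _ in range(100):
            step_dynamics(plate, np.zeros(2), 0.001)
        assert plate.rates.max() > 0

    def test_timeout_raises(self):
        plate = StripePlate()
        with pytest.raises(PatternFormationError):
            relax_to_pattern(plate, max_duration=0.001, seed=0)

    def test_realized_period_is_most_unstable_mode(self, formed_plate):
        f = np.abs(np.fft.rfft(formed_plate.rates - formed_plate.rates.mean()))
        mode = np.argmax(f[1:]) + 1
        assert 120 / mode == pytest.approx(most_unstable_period(120, 20.0))


class TestPhase:
    def test_matched_filter_recovers_known_phase(self):
        per = 30.0
        pos = np.arange(120)
        for p in (0.0, 7.3, 29.9):
            rates = 1.0 + np.cos(2 * np.pi * (pos - p) / per)
            d = (estimate_phase(rates, per) - p + per / 2) % per - per / 2
            assert abs(d) < 1e-6

    def test_roll_shifts_phase_by_one_cell(self, formed_plate):
        p0 = estimate_phase(formed_plate)
        p1 = estimate_phase(np.roll(formed_plate.rates, 1), formed_plate.pattern_period)
        per = formed_plate.pattern_period
        assert (p1 - p0) % per == pytest.approx(1.0, abs=1e-9)

    def test_uniform_rates_have_no_phase(self):
        with pytest.raises(UndefinedPhaseError):
            estimate_phase(np.ones(120), 30.0)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-14.9, 14.9), min_size=1, max_size=30))
    def test_tracker_unwraps_any_subcritical_increments(self, increments):
        per = 30.0
        tracker = PhaseTracker(per, 0.0)
        true = 0.0
        for d in increments:
            true += d
            tracker.update(true % per)
        assert tracker.cumulative == pytest.approx(true, abs=1e-9)


class TestCalibration:
    def test_roam_calibration_is_linear(self, calibrated_plate):
        _, result = calibrated_plate
        assert result.r >= 0.999
        assert result.max_residual < 0.02

    def test_straight_run_gain_matches_direct_ratio(self, formed_plate):
        """Constant-speed run: OLS gain equals displacement / phase advance."""
        plate = formed_plate.copy()
        speed, T, dt = 0.3, 30.0, 0.1
        n = int(T / dt)
        t = dt * np.arange(n + 1)
        traj = TrajectorySeries(
            t, speed * t, np.zeros(n + 1),
            np.full(n + 1, speed), np.zeros(n + 1),
        )
        result = calibrate_displacement_gain(plate, traj)
        direct = (speed * T) / (result.phase_track[-1] - result.phase_track[0])
        assert result.displacement_gain == pytest.approx(direct, rel=1e-2)

    def test_too_short_trajectory_rejected(self, formed_plate):
        traj = generate_random_walk(Arena(1, 1), 1.0, 0.1, seed=0)
        with pytest.raises(ValueError, match="too short"):
            calibrate_displacement_gain(formed_plate.copy(), traj)

    def test_single_cell_fires_in_bands(self, calibrated_plate):
        """Firing positions of one cell lie on stripes: periodic along the
        plate direction (period L), not periodic orthogonally."""
        plate, _ = calibrated_plate
        plate = plate.copy()
        L = plate.physical_period
        traj = generate_random_walk(Arena(1.0, 1.0), 40.0, 0.1, seed=21)
        cell = 0
        fired = []
        vels = traj.velocities
        for i in range(len(traj) - 1):
            B = forward_input(plate, vels[i])
            for _ in range(100):
                plate.rates = step_rates(plate.weights, plate.rates, B, 0.001, plate.tau)
            if plate.rates[cell] > 0.8 * plate.rates.max():
                fired.append(traj.positions[i + 1])
        fired = np.asarray(fired)
        assert len(fired) > 30
        u = plate.direction
        along = fired @ u
        ortho = fired @ np.array([-u[1], u[0]])
        conc_along = np.abs(np.mean(np.exp(2j * np.pi * along / L)))
        conc_ortho = np.abs(np.mean(np.exp(2j * np.pi * ortho / L)))
        assert conc_along > 0.8       # tightly clustered mod L along theta
        assert conc_ortho < 0.5       # no comparable periodicity across theta
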