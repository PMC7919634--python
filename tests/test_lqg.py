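"""Plant assembly, Kalman filter, receding-horizon control, ground truth."""

import numpy as np
import pytest
from scipy.linalg import solve_discrete_are

from trackinfo import (
    KalmanState,
    SignalConfig,
    build_plant,
    generate_target,
    ground_truth_tfb,
    ground_truth_tff,
    kalman_step,
    mpc_control,
    performance_lag,
    simulate_tracking,
    te_latency_curve,
)
from trackinfo.lqg import PlantModel


def _tiny_plant(A, B, C, Q, R, Qc=None, Rc=None, horizon=2):
    n = A.shape[0]
    return PlantModel(
        A=A, B=B, C=C, Q_proc=Q, R_obs=R,
        Q_cost=np.eye(n) if Qc is None else Qc,
        R_cost=np.eye(B.shape[1]) if Rc is None else Rc,
        horizon=horizon, visual_delay=0, motor_delay=0, target_phi=(0.0, 0.0),
        idx_target_prev=0, idx_target_cur=0, idx_tap=0,
        idx_joy_prev=0, idx_joy_cur=0, idx_error=0,
    )


class TestBuildPlant:
    @pytest.mark.parametrize("vd,md", [(0, 0), (10, 4), (5, 0), (0, 3), (15, 4)])
    def test_state_dimension_layout(self, vd, md):
        plant = build_plant(visual_delay=vd, motor_delay=md, horizon=md + 3)
        assert plant.n_states == 2 + vd + md + 2 + 1

    def test_zero_delay_joystick_core_rows(self):
        plant = build_plant(visual_delay=0, motor_delay=0, horizon=3)
        jidx = [plant.idx_joy_prev, plant.idx_joy_cur]
        np.testing.assert_allclose(
            plant.A[np.ix_(jidx, jidx)], [[0.0, 1.0], [-0.01, 0.81]]
        )

    def test_visual_delay_line_is_a_shift_register(self):
        vd = 6
        plant = build_plant(visual_delay=vd, motor_delay=0, horizon=3)
        line = [plant.idx_target_cur] + list(range(2, 2 + vd))
        M = np.zeros((vd + 1, vd + 1))
        for i, row in enumerate(line):
            for j, col in enumerate(line):
                if row != plant.idx_target_cur:
                    M[i, j] = plant.A[row, col]
        # injecting a value at the head reaches the output tap in exactly vd steps
        e0 = np.eye(vd + 1)[0]
        out = np.linalg.matrix_power(M, vd) @ e0
        assert out[-1] == 1.0 and np.count_nonzero(out) == 1
        assert plant.idx_tap == 2 + vd - 1

    def test_error_row_couples_tap_and_joystick(self):
        plant = build_plant(visual_delay=4, motor_delay=2, horizon=5)
        row = plant.A[plant.idx_error]
        assert row[plant.idx_tap] == 1.0 and row[plant.idx_joy_cur] == -1.0
        assert np.count_nonzero(row) == 2
        cur = build_plant(visual_delay=4, motor_delay=2, horizon=5,
                          error_reference="current")
        assert cur.A[cur.idx_error, cur.idx_target_cur] == 1.0

    def test_nonconformable_blocks_are_named(self):
        with pytest.raises(ValueError, match="spring_mass_coeffs"):
            build_plant(spring_mass_coeffs=(1.0, 2.0, 3.0))
        plant = build_plant(horizon=6)
        with pytest.raises(ValueError, match="R_obs"):
            PlantModel(
                A=plant.A, B=plant.B, C=plant.C, Q_proc=plant.Q_proc,
                R_obs=np.eye(3), Q_cost=plant.Q_cost, R_cost=plant.R_cost,
                horizon=6, visual_delay=10, motor_delay=4, target_phi=(0, 0),
            )

    def test_horizon_must_see_past_motor_delay(self):
        with pytest.raises(ValueError, match="horizon"):
            build_plant(motor_delay=8, horizon=8)


class TestKalman:
    def test_noiseless_filter_tracks_exactly(self, rng):
        A = np.array([[0.9, 0.2], [0.0, 0.7]])
        C = np.eye(2)
        plant = _tiny_plant(A, np.zeros((2, 1)), C, np.zeros((2, 2)), 1e-14 * np.eye(2))
        s = np.array([1.0, -0.5])
        state = KalmanState(mean=s.copy(), covariance=np.zeros((2, 2)))
        for _ in range(20):
            s = A @ s
            state = kalman_step(state, C @ s, plant)
            np.testing.assert_allclose(state.mean, s, atol=1e-8)

    def test_scalar_riccati_closed_form(self):
        a, c, q, r = 0.95, 1.0, 0.3, 0.5
        plant = _tiny_plant(
            np.array([[a]]), np.zeros((1, 1)), np.array([[c]]),
            np.array([[q]]), np.array([[r]]),
        )
        # p = a^2 p r/(c^2 p + r) + q  =>  quadratic in p, take the + root
        A2, B2 = a * a, c * c
        coef = [B2, r - A2 * r - B2 * q, -q * r]
        root = max(np.roots(coef))
        assert plant.kalman_steady_prior()[0, 0] == pytest.approx(root, abs=1e-9)

    def test_steady_state_matches_dare_oracle(self, rng):
        A = np.array([[0.8, 0.1, 0.0], [0.0, 0.9, 0.2], [0.1, 0.0, 0.5]])
        C = np.array([[1.0, 0.0, 1.0]])
        Q = np.diag([0.2, 0.1, 0.3])
        R = np.array([[0.4]])
        plant = _tiny_plant(A, np.zeros((3, 1)), C, Q, R)
        oracle = solve_discrete_are(A.T, C.T, Q, R)
        np.testing.assert_allclose(plant.kalman_steady_prior(), oracle, atol=1e-6)

    def test_covariance_stays_symmetric_psd(self, rng):
        plant = build_plant(horizon=6)
        state = KalmanState(
            mean=np.zeros(plant.n_states), covariance=np.eye(plant.n_states)
        )
        for _ in range(1_000):
            obs = rng.normal(size=2)
            state = kalman_step(state, obs, plant)
        P = state.covariance
        assert np.max(np.abs(P - P.T)) < 1e-10
        assert np.min(np.linalg.eigvalsh(P)) > -1e-12

    def test_observation_dimension_checked(self):
        plant = build_plant(horizon=6)
        state = KalmanState(np.zeros(plant.n_states), np.eye(plant.n_states))
        with pytest.raises(ValueError, match="observation dimension"):
            kalman_step(state, np.zeros(3), plant)


class TestMPC:
    def test_zero_state_gives_zero_control(self):
        plant = build_plant(horizon=8)
        assert mpc_control(np.zeros(plant.n_states), plant) == pytest.approx(0.0)

    def test_single_step_horizon_closed_form(self):
        A = np.array([[0.9, 0.3], [0.0, 0.8]])
        B = np.array([[0.0], [1.0]])
        Q = np.diag([2.0, 1.0])
        R = np.array([[0.5]])
        plant = _tiny_plant(A, B, np.eye(2), np.eye(2), np.eye(2), Qc=Q, Rc=R, horizon=1)
        s = np.array([1.0, -2.0])
        expected = -np.linalg.solve(B.T @ Q @ B + R, B.T @ Q @ A @ s)
        np.testing.assert_allclose(mpc_control(s, plant), expected, atol=1e-12)

    def test_long_horizon_approaches_lqr_gain(self):
        A = np.array([[1.0, 0.1], [0.0, 0.95]])
        B = np.array([[0.0], [0.1]])
        Q = np.diag([1.0, 0.1])
        R = np.array([[0.01]])
        P = solve_discrete_are(A, B, Q, R)
        K_lqr = np.linalg.solve(R + B.T @ P @ B, B.T @ P @ A)
        plant = _tiny_plant(A, B, np.eye(2), np.eye(2), np.eye(2), Qc=Q, Rc=R,
                            horizon=300)
        np.testing.assert_allclose(plant.mpc_gain(), K_lqr, atol=1e-6)


_SIM_CFG = SignalConfig(a1=32.0, n_frames=8_000, seed=31, noise_sd=32.0 * 0.028)


@pytest.fixture(scope="module")
def sim_run():
    # TE delay recovery needs a complex (weakly predictable) target, which is
    # also the condition the VMD estimator is meant for
    plant = build_plant(target_model=_SIM_CFG)
    return plant, simulate_tracking(plant, generate_target(_SIM_CFG), seed=32)


class TestSimulation:
    def test_same_seed_identical_runs(self):
        cfg = SignalConfig(a1=8.0, n_frames=2_000, seed=7, noise_sd=0.05)
        plant = build_plant(target_model=cfg, visual_delay=4, motor_delay=2, horizon=6)
        r1 = simulate_tracking(plant, generate_target(cfg), seed=9, transient=200)
        r2 = simulate_tracking(plant, generate_target(cfg), seed=9, transient=200)
        np.testing.assert_array_equal(r1.pair.tracking, r2.pair.tracking)
        np.testing.assert_array_equal(r1.controls, r2.controls)

    def test_effective_vmd_is_total_loop_latency(self):
        for vd, md in [(10, 4), (6, 2), (12, 0)]:
            plant = build_plant(visual_delay=vd, motor_delay=md, horizon=md + 5)
            assert plant.effective_vmd() == vd + md + 1

    def test_target_is_replayed_exactly(self, sim_run):
        _, run = sim_run
        target = generate_target(_SIM_CFG)
        np.testing.assert_allclose(run.pair.target, target.positions[500:], atol=1e-9)

    def test_cursor_stays_bounded(self, sim_run):
        _, run = sim_run
        assert np.max(np.abs(run.pair.tracking)) < 100 * np.std(run.pair.target)

    def test_estimated_feedback_below_ground_truth(self, sim_run):
        """TFB upper-bounds the copula-estimated IFB (information is lost
        downstream of the filter)."""
        from trackinfo import compute_ifb

        plant, run = sim_run
        ifb = compute_ifb(run.pair, run.true_vmd)
        assert ifb <= run.ground_truth[0] + 0.05

    def test_prediction_compensates_delay_under_current_error_objective(self):
        """With the objective on the *current* target, a predictable target
        lets the controller act ahead: performance lag < effective VMD."""
        cfg = SignalConfig(a1=0.5, n_frames=6_000, seed=41, noise_sd=0.5 * 0.0032)
        plant = build_plant(target_model=cfg, error_reference="current")
        run = simulate_tracking(plant, generate_target(cfg), seed=42)
        assert performance_lag(run.pair, 40) < run.true_vmd

    def test_lag_ratio_grows_with_signal_complexity(self):
        lags = {}
        for a1, innov in [(0.5, 0.0032), (32.0, 0.028)]:
            cfg = SignalConfig(a1=a1, n_frames=6_000, seed=43, noise_sd=a1 * innov)
            plant = build_plant(target_model=cfg)
            run = simulate_tracking(plant, generate_target(cfg), seed=44)
            lags[a1] = performance_lag(run.pair, 40) / run.true_vmd
        assert lags[32.0] > lags[0.5]

    def test_te_peak_recovers_loop_latency(self, sim_run):
        plant, run = sim_run
        curve = te_latency_curve(run.pair, 2, 30)
        assert curve.peak_delay == run.true_vmd


class TestGroundTruth:
    def test_tfb_scalar_closed_form(self):
        c, sig2, r = 1.5, 0.4, 0.2
        plant = _tiny_plant(
            np.array([[0.9]]), np.zeros((1, 1)), np.array([[c]]),
            np.array([[0.1]]), np.array([[r]]),
        )
        tfb = ground_truth_tfb(np.array([[sig2]]), plant)
        assert tfb == pytest.approx(0.5 * np.log2(1 + c**2 * sig2 / r))

    def test_tfb_vanishes_for_uninformative_observations(self, sim_run):
        plant, run = sim_run
        big_r = build_plant(target_model=SignalConfig(a1=8.0, noise_sd=8 * 0.007),
                            noise_covs={"obs": 1e6})
        assert ground_truth_tfb(big_r.kalman_steady_prior(), big_r) < 1e-3
        zero_sigma = np.zeros((plant.n_states, plant.n_states))
        assert ground_truth_tfb(zero_sigma, plant) == pytest.approx(0.0)

    def test_tff_zero_when_state_cov_equals_process_noise(self):
        plant = build_plant(horizon=6)
        idx = plant.core_indices
        sigma = np.zeros((plant.n_states, plant.n_states))
        sigma[np.ix_(idx, idx)] = plant.Q_proc[np.ix_(idx, idx)]
        assert ground_truth_tff(sigma, plant) == pytest.approx(0.0)

    def test_tff_scalar_arithmetic_and_monotonicity(self):
        a = np.array([[0.9]])
        mk = lambda q: _tiny_plant(a, np.zeros((1, 1)), np.array([[1.0]]),
                                   np.array([[q]]), np.array([[0.1]]))
        sigma = np.array([[2.0]])
        assert ground_truth_tff(sigma, mk(0.5)) == pytest.approx(0.5 * np.log2(2.0 / 0.5))
        assert ground_truth_tff(sigma, mk(0.1)) > ground_truth_tff(sigma, mk(0.5))

    def test_singular_noise_rejected(self):
        plant = _tiny_plant(np.array([[0.9]]), np.zeros((1, 1)), np.array([[1.0]]),
                            np.array([[0.2]]), np.array([[0.0]]))
        with pytest.raises(ValueError, match="singular"):
            ground_truth_tfb(np.array([[1.0]]), plant)
        zeroq = _tiny_plant(np.array([[0.9]]), np.zeros((1, 1)), np.array([[1.0]]),
                            np.array([[0.0]]), np.array([[0.1]]))
        with pytest.raises(ValueError):
            ground_truth_tff(np.array([[1.0]]), zeroq)
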