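"""Delay-augmented LQG simulator of the visuomotor tracking task.

The task is modelled as a discrete-time linear state-space system at the
display frame rate.  The state stacks, in order:

* the target AR(2) core ``[x_{t-1}, x_t]`` (the same second-order resonator
  the signal generator uses),
* a visual delay line of length ``visual_delay`` whose tail tap holds
  ``x_{t - visual_delay}`` — the only target value the observer ever sees,
* a motor delay line of length ``motor_delay`` carrying issued controls to
  the joystick,
* the joystick spring-mass core ``[j_{t-1}, j_t]`` with transition rows
  ``[0, 1]`` and ``[-0.01, 0.81]``,
* a scalar error state ``e_t = x_{t-1} - j_{t-1}`` coupling the current
  target and joystick positions.

The observation is the delayed target tap plus the joystick position (the
joystick is assumed known up to noise through efference copy), both corrupted
by Gaussian noise.  A Kalman filter tracks the full state — in particular it
extrapolates the *current* target position from the delayed tap using the
known target dynamics, which is where predictive (feedforward) behaviour
comes from.  Control is a receding-horizon linear-quadratic law penalizing
the error state: the batch finite-horizon problem is solved once,

    u* = -(Gamma' Qbar Gamma + Rbar)^{-1} Gamma' Qbar Ahat s,

and the first control of the optimal sequence is applied each step.

Model-internal ground truth for the information measures:

    TFB = 1/2 log2( |C P C' + R| / |R| )   (information the filter gains per
                                            observation; P is the steady-state
                                            prior error covariance)
    TFF = 1/2 log2( |Sigma| / |Q| )        (information the past state carries
                                            about the present, evaluated on
                                            the noise-driven coordinates)

Both upper-bound the copula-estimated IFB/IFF computed from the simulated
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decomposition import TrajectoryPair
from .exceptions import InstabilityError
from .signals import SignalConfig, TargetSignal, ar2_coefficients

__all__ = [
    "PlantModel",
    "KalmanState",
    "KalmanTrace",
    "SimulationRun",
    "build_plant",
    "kalman_step",
    "mpc_control",
    "simulate_tracking",
    "ground_truth_tfb",
    "ground_truth_tff",
]

_LN2 = float(np.log(2.0))

#: Joystick spring-mass transition row printed in the plant definition:
#: j_t = 0.81 j_{t-1} - 0.01 j_{t-2}.
DEFAULT_SPRING_MASS = (-0.01, 0.81)


@dataclass
class PlantModel:
    """Delay-augmented plant matrices plus noise and cost parameters.

    Built by :func:`build_plant`; carries index bookkeeping for the block
    layout and caches the MPC gain and steady-state Kalman quantities.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    Q_proc: np.ndarray
    R_obs: np.ndarray
    Q_cost: np.ndarray
    R_cost: np.ndarray
    horizon: int
    visual_delay: int
    motor_delay: int
    target_phi: tuple[float, float]
    idx_target_prev: int = 0
    idx_target_cur: int = 1
    idx_tap: int = 1
    idx_joy_prev: int = -1
    idx_joy_cur: int = -1
    idx_error: int = -1
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = self.A.shape[0]
        checks = {
            "A": self.A.shape == (n, n),
            "B": self.B.shape[0] == n,
            "C": self.C.shape[1] == n,
            "Q_proc": self.Q_proc.shape == (n, n),
            "R_obs": self.R_obs.shape == (self.C.shape[0], self.C.shape[0]),
            "Q_cost": self.Q_cost.shape == (n, n),
            "R_cost": self.R_cost.shape == (self.B.shape[1], self.B.shape[1]),
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"non-conformable plant blocks: {', '.join(bad)}")
        for name, m in (("Q_cost", self.Q_cost), ("R_cost", self.R_cost)):
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(m)) < -1e-12:
                raise ValueError(f"{name} must be positive semidefinite")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.visual_delay < 0 or self.motor_delay < 0:
            raise ValueError("delays must be non-negative")

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_controls(self) -> int:
        return self.B.shape[1]

    @property
    def noise_driven_indices(self) -> np.ndarray:
        """State coordinates that carry process noise (target, joystick, error
        positions); delay lines and lagged copies are deterministic."""
        return np.flatnonzero(np.diag(self.Q_proc) > 0)

    @property
    def core_indices(self) -> np.ndarray:
        """The physical dynamic-core coordinates: current target and joystick
        positions.  The feedforward ground truth is evaluated here — the
        error state is a derived linear combination of these two (plus an
        arbitrary-scale conditioning jitter), so including it would
        double-count coordinates rather than add dynamics."""
        return np.unique([self.idx_target_cur, self.idx_joy_cur])

    # -- receding-horizon control ------------------------------------------
    def mpc_matrices(self):
        """Horizon-stacked prediction matrices (Ahat, Gamma, Qbar, Rbar)."""
        if "mpc_matrices" not in self._cache:
            n, m, N = self.n_states, self.n_controls, self.horizon
            powers = [np.eye(n)]
            for _ in range(N):
                powers.append(self.A @ powers[-1])
            ahat = np.vstack(powers[1:])  # A, A^2, ..., A^N
            gamma = np.zeros((n * N, m * N))
            for i in range(1, N + 1):  # s_{t+i} rows
                for j in range(i):  # u_{t+j} columns
                    gamma[(i - 1) * n : i * n, j * m : (j + 1) * m] = (
                        powers[i - 1 - j] @ self.B
                    )
            qbar = np.kron(np.eye(N), self.Q_cost)
            rbar = np.kron(np.eye(N), self.R_cost)
            self._cache["mpc_matrices"] = (ahat, gamma, qbar, rbar)
        return self._cache["mpc_matrices"]

    def mpc_gain(self) -> np.ndarray:
        """First-block gain K of the receding-horizon law u = -K s."""
        if "mpc_gain" not in self._cache:
            ahat, gamma, qbar, rbar = self.mpc_matrices()
            H = gamma.T @ qbar @ gamma + rbar
            F = gamma.T @ qbar @ ahat
            if np.linalg.cond(H) > 1e14:
                raise np.linalg.LinAlgError(
                    "horizon cost matrix H is (near-)singular; increase the "
                    "control cost R_cost"
                )
            self._cache["mpc_gain"] = np.linalg.solve(H, F)[: self.n_controls]
        return self._cache["mpc_gain"]

    # -- steady-state Kalman quantities ------------------------------------
    def kalman_steady_prior(self, tol: float = 1e-12, max_iter: int = 200_000) -> np.ndarray:
        """Steady-state prior error covariance (fixed point of the Riccati
        recursion), found by iterating the filter covariance update."""
        if "steady_prior" not in self._cache:
            P = np.eye(self.n_states)
            for _ in range(max_iter):
                S = self.C @ P @ self.C.T + self.R_obs
                K = np.linalg.solve(S, self.C @ P).T
                Ppost = P - K @ self.C @ P
                Pn = self.A @ Ppost @ self.A.T + self.Q_proc
                Pn = 0.5 * (Pn + Pn.T)
                delta = np.max(np.abs(Pn - P))
                P = Pn
                if delta < tol:
                    break
            else:
                raise RuntimeError("Riccati recursion did not converge")
            self._cache["steady_prior"] = P
        return self._cache["steady_prior"]

    def kalman_steady_gain(self) -> np.ndarray:
        if "steady_gain" not in self._cache:
            P = self.kalman_steady_prior()
            S = self.C @ P @ self.C.T + self.R_obs
            self._cache["steady_gain"] = np.linalg.solve(S, self.C @ P).T
        return self._cache["steady_gain"]

    def effective_vmd(self) -> int:
        """Total input-to-output latency of the closed loop, in frames.

        Determined by injecting a unit target innovation into the noiseless
        closed loop and returning the first frame at which the joystick
        responds.  Equals visual delay + motor delay + the one-frame latency
        of the joystick plant under the adopted layout.
        """
        if "effective_vmd" not in self._cache:
            Kf, Km = self.kalman_steady_gain(), self.mpc_gain()
            n = self.n_states
            horizon = self.visual_delay + self.motor_delay + 40
            s = np.zeros(n)
            mean = np.zeros(n)
            u = np.zeros(self.n_controls)
            response = np.zeros(horizon)
            for t in range(horizon):
                s = self.A @ s + self.B @ u
                if t == 0:
                    s[self.idx_target_cur] += 1.0
                obs = self.C @ s
                mp = self.A @ mean + self.B @ u
                mean = mp + Kf @ (obs - self.C @ mp)
                u = -Km @ mean
                response[t] = s[self.idx_joy_cur]
            peak = np.max(np.abs(response))
            if peak == 0:
                raise InstabilityError("closed loop shows no joystick response")
            self._cache["effective_vmd"] = int(np.flatnonzero(np.abs(response) > 1e-9 * peak)[0])
        return self._cache["effective_vmd"]


@dataclass(frozen=True)
class KalmanState:
    """State estimate mean and covariance."""

    mean: np.ndarray
    covariance: np.ndarray


@dataclass(frozen=True)
class KalmanTrace:
    """Per-step filter means plus the steady-state prior covariance."""

    means: np.ndarray  # (T, n)
    prior_covariance: np.ndarray  # (n, n)


@dataclass(frozen=True)
class SimulationRun:
    """Closed-loop rollout with internal traces and ground-truth information."""

    pair: TrajectoryPair
    controls: np.ndarray
    state_trace: np.ndarray  # true states, (T, n)
    kalman_trace: KalmanTrace
    ground_truth: tuple[float, float]  # (TFB, TFF) bits/sample
    true_vmd: int


def build_plant(
    spring_mass_coeffs: tuple[float, float] = DEFAULT_SPRING_MASS,
    target_model: SignalConfig | tuple[float, float, float] | None = None,
    visual_delay: int = 10,
    motor_delay: int = 4,
    horizon: int = 12,
    cost_weights: tuple[float, float] = (1.0, 1e-3),
    noise_covs: dict | None = None,
    error_reference: str = "delayed",
) -> PlantModel:
    """Assemble the delay-augmented plant.

    Parameters
    ----------
    spring_mass_coeffs
        ``(c1, c2)`` of the joystick row ``j_t = c2 j_{t-1} + c1 j_{t-2} + u``.
    target_model
        Either a :class:`SignalConfig` (AR coefficients and innovation
        variance are derived from it) or a tuple ``(phi1, phi2,
        innovation_var)``.  Defaults to ``SignalConfig(a1=1.0)``.
    visual_delay, motor_delay
        Delay-line lengths in frames.
    horizon
        MPC horizon N; must comfortably exceed the motor delay or the
        controller cannot see any effect of its actions.
    cost_weights
        ``(error_weight, control_weight)`` entering Q_cost (on the error
        state only) and R_cost.
    noise_covs
        Optional overrides: ``target`` (innovation variance; defaults to the
        target model's), ``motor``, ``error`` (process-noise variances) and
        ``obs`` (per-channel observation-noise variance).
    error_reference
        Which target position the error state (and hence the regulation
        objective) is coupled to: ``"delayed"`` (default) uses the visually
        observed tap ``x_{t-visual_delay}``, so the controller pursues the
        target it actually sees and the tracking lag sits at or above the
        effective VMD; ``"current"`` couples the true current position
        ``x_t``, an idealized objective under which predictive extrapolation
        can drive the lag below the VMD.

    The state dimension is ``2 + visual_delay + motor_delay + 2 + 1``.
    """
    try:
        c1, c2 = (float(v) for v in spring_mass_coeffs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"spring_mass_coeffs must be two scalars: {exc}") from None
    if target_model is None:
        target_model = SignalConfig(a1=1.0)
    if isinstance(target_model, SignalConfig):
        phi1, phi2 = ar2_coefficients(target_model.a1, target_model.variant)
        target_var = (target_model.noise_sd / target_model.a1) ** 2
    else:
        phi1, phi2, target_var = (float(v) for v in target_model)
    noise = {"motor": 1e-4, "error": 1e-6, "obs": 2.5e-3, "target": target_var}
    noise.update(noise_covs or {})
    if horizon <= motor_delay + 1:
        raise ValueError(
            f"horizon={horizon} cannot see past motor_delay={motor_delay}; "
            "use horizon > motor_delay + 1"
        )

    vd, md = visual_delay, motor_delay
    n = 5 + vd + md
    i_xp, i_xc = 0, 1
    vis = list(range(2, 2 + vd))  # v_1..v_vd
    mot = list(range(2 + vd, 2 + vd + md))  # m_1..m_md
    i_jp, i_jc, i_e = 2 + vd + md, 3 + vd + md, 4 + vd + md
    i_tap = vis[-1] if vd else i_xc

    A = np.zeros((n, n))
    A[i_xp, i_xc] = 1.0
    A[i_xc, i_xc], A[i_xc, i_xp] = phi1, phi2
    prev = i_xc
    for iv in vis:  # visual shift register off the current target position
        A[iv, prev] = 1.0
        prev = iv
    B = np.zeros((n, 1))
    if md:
        B[mot[0], 0] = 1.0
        for k in range(1, md):
            A[mot[k], mot[k - 1]] = 1.0
    A[i_jp, i_jc] = 1.0
    A[i_jc, i_jc], A[i_jc, i_jp] = c2, c1
    if md:
        A[i_jc, mot[-1]] = 1.0
    else:
        B[i_jc, 0] = 1.0
    if error_reference == "delayed":
        A[i_e, i_tap] = 1.0
    elif error_reference == "current":
        A[i_e, i_xc] = 1.0
    else:
        raise ValueError(f"unknown error_reference {error_reference!r}")
    A[i_e, i_jc] = -1.0

    C = np.zeros((2, n))
    C[0, i_tap] = 1.0
    C[1, i_jc] = 1.0

    Q_proc = np.zeros((n, n))
    Q_proc[i_xc, i_xc] = noise["target"]
    Q_proc[i_jc, i_jc] = noise["motor"]
    Q_proc[i_e, i_e] = noise["error"]
    R_obs = np.eye(2) * noise["obs"]
    Q_cost = np.zeros((n, n))
    Q_cost[i_e, i_e] = cost_weights[0]
    R_cost = np.array([[cost_weights[1]]])

    return PlantModel(
        A=A, B=B, C=C, Q_proc=Q_proc, R_obs=R_obs, Q_cost=Q_cost, R_cost=R_cost,
        horizon=horizon, visual_delay=vd, motor_delay=md, target_phi=(phi1, phi2),
        idx_target_prev=i_xp, idx_target_cur=i_xc, idx_tap=i_tap,
        idx_joy_prev=i_jp, idx_joy_cur=i_jc, idx_error=i_e,
    )


def kalman_step(
    state: KalmanState, observation: np.ndarray, plant: PlantModel, control=None
) -> KalmanState:
    """One predict-update cycle of the Kalman filter.

    Uses the Joseph-form covariance update, which preserves symmetry and
    positive semidefiniteness; the returned covariance is re-symmetrized.
    """
    obs = np.atleast_1d(np.asarray(observation, float))
    if obs.shape[0] != plant.C.shape[0]:
        raise ValueError(
            f"observation dimension {obs.shape[0]} does not match C rows "
            f"{plant.C.shape[0]}"
        )
    u = np.zeros(plant.n_controls) if control is None else np.atleast_1d(control)
    A, C, Q, R = plant.A, plant.C, plant.Q_proc, plant.R_obs
    mp = A @ state.mean + plant.B @ u
    Pp = A @ state.covariance @ A.T + Q
    S = C @ Pp @ C.T + R
    if np.linalg.cond(S) > 1e14:
        raise np.linalg.LinAlgError("innovation covariance is singular")
    K = np.linalg.solve(S, C @ Pp).T
    mean = mp + K @ (obs - C @ mp)
    IKC = np.eye(plant.n_states) - K @ C
    P = IKC @ Pp @ IKC.T + K @ R @ K.T
    return KalmanState(mean=mean, covariance=0.5 * (P + P.T))


def mpc_control(state_mean: np.ndarray, plant: PlantModel) -> np.ndarray:
    """Receding-horizon control: the first element of the optimal batch
    control sequence, a linear function of the state estimate."""
    return -plant.mpc_gain() @ np.asarray(state_mean, float)


def simulate_tracking(
    plant: PlantModel,
    target: TargetSignal,
    seed: int | None = None,
    transient: int = 500,
) -> SimulationRun:
    """Closed-loop rollout of the tracking task against a given target.

    The target trajectory is replayed exactly: its innovations (with respect
    to the plant's target dynamics) are injected as the target-row process
    noise.  Motor and error-state noise and observation noise are drawn from
    ``seed``.  The filter runs at the steady-state Kalman gain; the first
    ``transient`` frames are discarded from the returned traces.
    """
    x = np.asarray(target.positions, float)
    T = x.size
    if T <= transient + 100:
        raise ValueError(f"target of length {T} too short for transient={transient}")
    phi1, phi2 = plant.target_phi
    w = np.empty(T)
    w[0] = x[0]
    w[1] = x[1] - phi1 * x[0]
    w[2:] = x[2:] - phi1 * x[1:-1] - phi2 * x[:-2]

    rng = np.random.default_rng(seed)
    sd_m = np.sqrt(plant.Q_proc[plant.idx_joy_cur, plant.idx_joy_cur])
    sd_e = np.sqrt(plant.Q_proc[plant.idx_error, plant.idx_error])
    obs_noise = rng.multivariate_normal(np.zeros(2), plant.R_obs, size=T)
    motor_noise = rng.normal(0.0, sd_m, size=T)
    error_noise = rng.normal(0.0, sd_e, size=T)

    Kf = plant.kalman_steady_gain()
    Km = plant.mpc_gain()
    A, B, C = plant.A, plant.B, plant.C
    n = plant.n_states
    bound = 1e6 * max(1.0, np.max(np.abs(x)))

    s = np.zeros(n)
    mean = np.zeros(n)
    u = np.zeros(plant.n_controls)
    states = np.empty((T, n))
    means = np.empty((T, n))
    controls = np.empty((T, plant.n_controls))
    cursor = np.empty(T)
    for t in range(T):
        s = A @ s + B @ u
        s[plant.idx_target_cur] += w[t]
        s[plant.idx_joy_cur] += motor_noise[t]
        s[plant.idx_error] += error_noise[t]
        obs = C @ s + obs_noise[t]
        mp = A @ mean + B @ u
        mean = mp + Kf @ (obs - C @ mp)
        u = -Km @ mean
        states[t] = s
        means[t] = mean
        controls[t] = u
        cursor[t] = s[plant.idx_joy_cur]
        if abs(cursor[t]) > bound:
            raise InstabilityError(
                f"closed-loop simulation diverged at frame {t} "
                f"(|cursor| > {bound:g}); check cost weights and delays"
            )

    pair = TrajectoryPair(
        target=x[transient:], tracking=cursor[transient:],
        frame_rate=target.config.frame_rate,
    )
    trace = KalmanTrace(means=means[transient:], prior_covariance=plant.kalman_steady_prior())
    run_states = states[transient:]
    tfb = ground_truth_tfb(trace, plant)
    tff = ground_truth_tff(run_states, plant)
    return SimulationRun(
        pair=pair, controls=controls[transient:], state_trace=run_states,
        kalman_trace=trace, ground_truth=(tfb, tff), true_vmd=plant.effective_vmd(),
    )


def ground_truth_tfb(kalman_trace, plant: PlantModel) -> float:
    """Ground-truth feedback information (bits/sample).

    The information each observation provides about the state at the filter's
    steady state: ``1/2 log2(|C P C' + R| / |R|)`` with P the steady-state
    prior error covariance.  Non-negative; zero when observations are
    uninformative (huge R) or the state is already known (P -> 0).
    """
    sign_r, ld_r = np.linalg.slogdet(plant.R_obs)
    if sign_r <= 0:
        raise ValueError("TFB undefined: observation-noise covariance is singular")
    P = (
        kalman_trace.prior_covariance
        if isinstance(kalman_trace, KalmanTrace)
        else np.asarray(kalman_trace, float)
    )
    S = plant.C @ P @ plant.C.T + plant.R_obs
    sign_s, ld_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("TFB undefined: innovation covariance is not positive definite")
    return float((ld_s - ld_r) / (2.0 * _LN2))


def ground_truth_tff(state_trace, plant: PlantModel) -> float:
    """Ground-truth feedforward information (bits/sample).

    The information the past state carries about the present,
    ``1/2 log2(|Sigma| / |Q|)``, with both determinants evaluated on the
    noise-driven dynamic cores (current target and joystick positions).  The
    deterministic delay-line states would make |Q| vanish, and the error
    state is a linear function of the two cores, so neither belongs in the
    determinant ratio.  ``state_trace`` may be a (T, n) trace of states past
    the transient — Sigma is then its sample covariance — or an (n, n)
    stationary covariance, or a :class:`SimulationRun`.
    """
    idx = plant.core_indices
    Qs = plant.Q_proc[np.ix_(idx, idx)]
    sign_q, ld_q = np.linalg.slogdet(Qs)
    if sign_q <= 0:
        raise ValueError("TFF undefined: process noise singular on the noise-driven subspace")
    if isinstance(state_trace, SimulationRun):
        state_trace = state_trace.state_trace
    arr = np.asarray(state_trace, float)
    n = plant.n_states
    if arr.shape == (n, n) and np.allclose(arr, arr.T):
        sigma = arr[np.ix_(idx, idx)]
    else:
        sigma = np.cov(arr[:, idx], rowvar=False, ddof=1)
    sign_s, ld_s = np.linalg.slogdet(np.atleast_2d(sigma))
    if sign_s <= 0:
        raise ValueError("TFF undefined: state covariance is not positive definite")
    return float((ld_s - ld_q) / (2.0 * _LN2))
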