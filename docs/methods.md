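# Methods

## Target signals

Targets are one-dimensional trajectories produced by passing Gaussian white
noise `ε` (SD `noise_sd`) through a narrowband second-order filter. The
shipped default is a stable AR(2) resonator

    x[t] = 2 r cos(θ) x[t-1] − r² x[t-2] + ε[t]/a1,   θ = π/100 rad/frame,
    r = 1 − 0.005·a1,

i.e. complex poles at radius `r` and angle `θ` (oscillation period 200 frames
≈ 3.3 s at 60 Hz). The single gain `a1 > 0` sets the noise pass-through and
hence predictability: small `a1` puts the poles near the unit circle (an
almost pure, fully predictable oscillation), large `a1` broadens the band.
Whatever `a1`, the process is exactly second-order — its partial
autocorrelation vanishes beyond lag 2 — which is the property the
information measures below rely on.

A literal variant of the defining recurrence, `a1·x[t] = ε[t] + a2·x[t-1] +
x[t-2]` with `a2 = −2a1·cos(θ)`, is available as `variant="printed"`. Its
characteristic polynomial `a1 z² + 2a1 cos(θ) z − 1` always has a root of
magnitude ≈ 2cos(θ) > 1, so generation with it raises `InstabilityError`; it
is retained for inspection only.

The recurrence starts from zero; a 500-frame burn-in (several times the
resonator's 1/(1−r) relaxation time for the default levels) is discarded.

**Amplitude normalization.** In the validation pipeline each complexity
level's driving noise is scaled so the stationary SD equals `amplitude`
(default 1 screen unit): `noise_sd = a1·amplitude/√G(a1)` where `G` is the
closed-form AR(2) variance gain. This mimics the experimental situation —
signals of every difficulty span the same screen range — and makes "harder"
mean "larger innovation share", not "larger excursions".

The default complexity sweep is `a1 ∈ {0.5, 2, 8, 32}`: four conditions,
geometrically spaced over roughly two decades of noise pass-through,
mirroring the wide difficulty spread typical of tracking experiments (human
feedback rates span an order of magnitude across conditions).

## Gaussian-copula information estimation

Every estimate begins with the probability integral transform per column:
average-ranked values are mapped to `rank/(N+1)` and through the
standard-normal quantile. This discards the marginals and keeps only the
dependence structure, so estimates are exactly invariant to strictly
increasing transforms of any input; because the Gaussian maximizes entropy
at fixed covariance, the estimate is a lower bound on the true MI for
non-Gaussian dependence.

MI and conditional MI are then covariance log-determinant expressions
(natural logs internally, reported in bits):

    I(X;Y)   = ½ ln( |Σ_X||Σ_Y| / |Σ_XY| )
    I(Y;X|Z) = ½ ln( |Σ_YZ||Σ_XZ| / (|Σ_Z||Σ_XYZ|) )

with 1/(N−1) covariances. Each sample `ln|S|` is bias-corrected by
subtracting the Wishart expectation offset

    bias(k, N) = k ln(2/(N−1)) + Σ_{i=1..k} ψ((N−i)/2),

where `ψ` is the digamma function. A variant omitting the `−k ln(N−1)` term
exists behind `bias_variant="printed"`; a Monte-Carlo test in the suite
confirms the shipped form matches the empirical expectation of `ln|S|` and
the variant does not. Uncorrected estimates are non-negative by Fischer's
inequality; corrected values can dip slightly below zero and are reported
unclamped. Perfectly dependent inputs make a joint covariance singular and
raise `DegenerateDataError` rather than returning infinities.

## The decomposition

For a trajectory pair at VMD `v` (frames):

    IFB    = I(Y_t ; X_{t−v}, X_{t−v−1} | Y_{t−v}, Y_{t−v−1}, Y_{t−1})
    Itotal = I(Y_t ; X_t, X_{t−1}, X_{t−v}, X_{t−v−1})
    IFF    = Itotal − IFB              (exact arithmetic identity)

Lag depths of 2 match the order-2 target; the extra `Y_{t−1}` conditioning
makes successive IFB samples independent, so `IFB × frame_rate` is a
bits-per-second rate. All lagged copies are taken within a single trial
(no cross-trial concatenation); per-condition values average per-trial
estimates.

**VMD estimation.** The transfer-entropy latency curve evaluates the IFB
form at each candidate delay `d ∈ [2, 30]` (covering human values of 14–16
frames with margin); the peak is the VMD estimate, ties broken toward the
smallest delay. Peak significance can be assessed against circular-shift
surrogates of the target (seeded; default 100 in `estimate_vmd`): a peak
less than 3 surrogate SDs above the curve median is flagged low-confidence,
and trials so flagged are excluded from the trial-averaged estimate. The
peak latency is informative only when the target is hard enough that
real-time feedback is actually engaged; for nearly deterministic targets the
curve is flat and the flag or the estimate's dispersion will say so.

**Performance lag** is the integer lag maximizing the cross-correlation of
the mean-removed series (smallest lag on ties). Frame quantization of this
lag is the resolution limit of everything built on it.

## The LQG tracking simulator

Discrete time at 60 Hz; state (dimension `2 + visual_delay + motor_delay +
2 + 1`) stacks:

| block | size | content |
|---|---|---|
| target core | 2 | `[x_{t−1}, x_t]`, the AR(2) resonator |
| visual delay line | `v_d` | shift register; tail tap holds `x_{t−v_d}` |
| motor delay line | `m_d` | shift register carrying issued controls |
| joystick core | 2 | `[j_{t−1}, j_t]`, rows `[0,1]` and `[−0.01, 0.81]` |
| error state | 1 | `e_t = x*_{t−1} − j_{t−1}` |

The observation is the delayed target tap plus the current joystick position
(efference copy), both with Gaussian noise. The error reference `x*` is the
**observed (delayed) target tap** by default (`error_reference="delayed"`):
the controller pursues the target it actually sees, which reproduces the
empirical regime where tracking lag sits near the full loop latency. The
idealized alternative (`"current"`) couples the true current position; under
it the Kalman filter's extrapolation lets the lag drop well below the VMD
for predictable targets. Both are available; the delayed coupling is the
validated default.

The filter is a standard Kalman filter; the steady-state gain (fixed point
of the Riccati recursion, iterated to 1e−12, verified against an independent
DARE solver to 1e−6) is used inside the simulation loop. Control is the
receding-horizon batch LQ law `u = −(ΓᵀQ̄Γ + R̄)⁻¹ΓᵀQ̄Â ŝ` (first block),
verified against the one-step closed form and the infinite-horizon LQR
limit. The horizon must exceed the motor delay by at least two frames or
the controller cannot see any effect of its actions; `build_plant` enforces
this.

`simulate_tracking` replays a generated target exactly by injecting its
innovations as the target-row process noise, so the simulated "screen"
matches the input trajectory sample for sample.

**Ground truth.** At the filter's steady state,

    TFB = ½ log₂( |C P C′ + R| / |R| )        (P: steady-state prior error
                                               covariance — the information
                                               gained per observation)
    TFF = ½ log₂( |Σ| / |Q| )                 (Σ: stationary covariance of the
                                               dynamic cores from the run's
                                               state trace; Q: their process
                                               noise)

Both are evaluated in bits/sample and upper-bound the copula estimates
(information is lost downstream of the filter). TFF's determinants are
restricted to the two dynamic-core coordinates (current target and joystick
positions): delay-line and lagged-copy coordinates carry no process noise
(the ratio would be undefined), and the error state is a linear function of
the two cores plus an arbitrary-scale conditioning jitter, so including it
would double-count coordinates and let a bookkeeping variable dominate a
physical quantity.

**Effective VMD.** The loop latency is visual delay + motor delay + one
frame of joystick-plant latency; it is measured, not assumed, by injecting a
unit target innovation into the noiseless closed loop and taking the first
frame of cursor response. Delay-recovery comparisons are correlations
against the implanted delay, since the constant plant offset is part of the
loop.

## Defaults and their reasons

| parameter | default | why |
|---|---|---|
| frame rate | 60 Hz | display rate of the task being modelled |
| trial length | 10⁴ frames (~2.8 min) | long enough for ~50 independent cycles of the slowest target |
| burn-in / transient | 500 frames each | several relaxation times of the slowest mode |
| visual + motor delay | 10 + 4 frames | effective VMD 15 frames ≈ 250 ms, the human range |
| horizon | 12 | exceeds motor delay with margin; near-asymptotic gain |
| observation noise SD | 0.05 | ~5% of the unit target SD (visual localization noise) |
| motor noise SD | 0.01 | ~1% cursor jitter |
| error-state jitter SD | 1e−3 | conditioning only; keeps the filter covariance positive definite |
| cost weights (error, control) | (1, 1e−3) | error-dominated objective with a small effort penalty |
| a1 levels × seeds | {0.5, 2, 8, 32} × 3 | see amplitude normalization above |

## What the synthetic data does and does not emulate

The generator and simulator reproduce the structural features the measures
depend on: second-order narrowband targets of controllable predictability,
an irreducible sensorimotor loop delay, noisy observation, and
prediction-capable control. They do not emulate signal-dependent motor
noise, nonlinear biomechanics, attention lapses, non-stationary delays, or
eye movements. Passing tests therefore demonstrate that the estimators
recover known information quantities and delays *in a linear-Gaussian world
with matched assumptions*; on human data the copula estimates remain valid
lower bounds, but ground-truth comparisons are unavailable by nature.

## Numerical choices and degenerate inputs

* Rank ties: average ranks; uniforms strictly inside (0,1) via `/(N+1)`.
* All argmax tie-breaks (TE peak, performance lag) choose the smallest lag.
* Constant columns, non-finite inputs, perfectly dependent inputs: explicit
  `DegenerateDataError` (no NaN propagation).
* Joseph-form covariance update plus re-symmetrization in `kalman_step`.
* Unstable recurrences and diverging closed loops raise `InstabilityError`
  naming the offending parameter; unstable sweep runs are excluded with a
  warning.
* The exponential lag fit is ordinary least squares on `log(PL/VMD)` vs IFB
  (rows with non-positive ratios excluded with a warning), back-transformed
  with 95% linear-fit CIs; its R² is reported on the original ratio scale.

## Known limitations

* The VMD estimate has one-frame resolution (17 ms at 60 Hz), and the
  performance lag inherits the same quantization; the exponential lag fit's
  R² is bounded by it when the lag spans only a few distinct frame values.
* The measures are tailored to order-2 targets; richer autocorrelation
  structures would need higher-order lag terms in both formulas.
* The copula estimator is a lower bound under non-Gaussian dependence, and
  conflates the motor command with the observed cursor (motor noise makes
  the feedback component a slight underestimate).
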