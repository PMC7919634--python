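# trackinfo

Feedback/feedforward information decomposition for visuomotor tracking.

## The problem

In a pursuit-tracking task a person watches a moving target and follows it
with a cursor. The information shared between target trajectory `X` and
tracking response `Y` has two distinct origins:

* a **feedback** route — visual input is processed in real time and converted
  to a motor correction, arriving after the irreducible **visuomotor delay**
  (VMD, ~250 ms); this is the channel that actually costs cognitive
  resources, because it transmits the *surprising* part of the signal;
* a **feedforward** route — the tracker has learned the target's dynamics and
  acts predictively; predictable structure is encoded "for free".

`trackinfo` separates the two. For a target with second-order
autocorrelation, with `v` the VMD in frames:

```
IFB    = I(Y_t ; X_{t-v}, X_{t-v-1} | Y_{t-v}, Y_{t-v-1}, Y_{t-1})
Itotal = I(Y_t ; X_t, X_{t-1}, X_{t-v}, X_{t-v-1})
IFF    = Itotal - IFB
```

`IFB` is a delayed, history-conditioned transfer entropy (bits/sample);
multiplied by the frame rate it is a real-time information processing rate in
bits/s. All quantities are estimated with a rank-based **Gaussian-copula**
estimator: each variable is mapped rank → uniform → standard-normal quantile,
and MI is computed from covariance log-determinants with an analytic
(Wishart/digamma) small-sample bias correction. Estimates are exactly
invariant to monotone marginal transforms and lower-bound the true MI.

The VMD itself is estimated from data as the peak latency of the transfer
entropy from target to tracking. The package also ships:

* a target-signal generator (white noise through a narrowband second-order
  filter, predictability controlled by one gain `a1`);
* a delay-augmented **LQG simulator** of the task (Kalman filter +
  receding-horizon quadratic control) that exposes model-internal ground
  truth `TFB = ½log₂|CΣC′+R|/|R|` and `TFF = ½log₂|Σ|/|Q|`, used to validate
  the estimators.

## Worked example

Simulate two tracking trials against a hard (weakly predictable) target,
estimate the VMD from the transfer-entropy peak, and decompose:

```
$ trackinfo simulate --a1 32 --n-trials 2 --seed 5 --out-dir runs/
wrote 2 run(s) to runs

$ trackinfo estimate-vmd --in runs/run_000.csv
{"vmd_mean": 15.0, "vmd_sd": 0.0, "per_trial": [15]}

$ trackinfo decompose --in runs/run_000.csv --vmd 15 --out report.json
IFB=1.3543 bits/sample (81.26 bits/s), IFF=1.3508, Itotal=2.7052 over 1 trial(s)
```

The estimated VMD (15 frames ≈ 250 ms at 60 Hz) recovers the simulator's
implanted visual+motor loop latency. Of the ~2.7 bits/sample the cursor
carries about the target, about half arrives through the delayed real-time
feedback channel (`IFB`) and the rest is predictive (`IFF`); for an easy
target (`--a1 0.5`) the balance tilts strongly toward `IFF`.

The same `decompose` command accepts any CSV with columns
`frame,target_x,cursor_x[,trial]`, e.g. experimental tracking data.

## Library API

```python
from trackinfo import (SignalConfig, generate_target, build_plant,
                       simulate_tracking, decompose, te_latency_curve,
                       SweepConfig, run_predictability_sweep)

cfg = SignalConfig(a1=8.0, n_frames=10_500, seed=0)
plant = build_plant(target_model=cfg)
run = simulate_tracking(plant, generate_target(cfg), seed=1)
print(decompose(run.pair, vmd=run.true_vmd))
```

See `docs/methods.md` for the model, estimator details and all defaults.

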