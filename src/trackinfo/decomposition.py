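"""Feedback/feedforward decomposition of target-tracking information.

A tracker can share information with the target trajectory through two routes:
a real-time feedback route, in which visual input drives the motor output
after the irreducible visuomotor delay (VMD), and a predictive feedforward
route, in which the tracker exploits the learned second-order dynamics of the
target and acts in advance.  With a second-order target the two routes are
captured by three quantities (all in bits per sample):

    IFB    = I(Y_t ; {X_{t-v}, X_{t-v-1}} | {Y_{t-v}, Y_{t-v-1}, Y_{t-1}})
    Itotal = I(Y_t ; {X_t, X_{t-1}, X_{t-v}, X_{t-v-1}})
    IFF    = Itotal - IFB

where v is the VMD in frames.  IFB is a transfer entropy (input past about
output present, given output past, with the extra Y_{t-1} conditioning making
successive samples independent); multiplied by the frame rate it is a
real-time information processing rate in bits/s.  The VMD itself is estimated
from data as the delay at which the transfer-entropy latency curve peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDataError
from .gcmi import cmi_copula, mi_copula

__all__ = [
    "TrajectoryPair",
    "InfoDecomposition",
    "TELatencyCurve",
    "VMDEstimate",
    "compute_ifb",
    "compute_itotal",
    "compute_iff",
    "decompose",
    "te_latency_curve",
    "estimate_vmd",
    "performance_lag",
    "rate_per_second",
]


@dataclass(frozen=True)
class TrajectoryPair:
    """Aligned target and tracking position series at a fixed frame rate."""

    target: np.ndarray
    tracking: np.ndarray
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        t = np.asarray(self.target, dtype=float)
        y = np.asarray(self.tracking, dtype=float)
        if t.ndim != 1 or y.ndim != 1:
            raise ValueError("target and tracking must be 1-d series")
        if t.size != y.size:
            raise ValueError(f"length mismatch: target {t.size} vs tracking {y.size}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise DegenerateDataError("trajectories contain non-finite values")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        object.__setattr__(self, "target", t)
        object.__setattr__(self, "tracking", y)

    def __len__(self) -> int:
        return self.target.size


@dataclass(frozen=True)
class InfoDecomposition:
    """IFB, Itotal and IFF (bits/sample) at a given VMD, plus the bits/s rate."""

    ifb: float
    itotal: float
    iff: float
    vmd: int
    ifb_per_second: float


@dataclass(frozen=True)
class TELatencyCurve:
    """Transfer entropy (bits/sample) as a function of candidate delay."""

    delays: np.ndarray
    te_values: np.ndarray
    peak_delay: int
    peak_value: float
    #: Standard error of the TE estimate from circular-shift surrogates of the
    #: target (None when no surrogates were run).
    surrogate_se: float | None = None
    #: True when the peak does not rise at least 3 surrogate SEs above the
    #: median of the curve; None when no surrogates were run.
    low_confidence: bool | None = None


@dataclass(frozen=True)
class VMDEstimate:
    """Trial-averaged VMD estimate with across-trial dispersion."""

    mean: float
    sd: float
    per_trial: tuple[int, ...]


def _check_vmd(pair: TrajectoryPair, vmd: int) -> None:
    if vmd < 2:
        raise ValueError(f"vmd must be >= 2 frames, got {vmd}")
    if vmd >= len(pair) / 10:
        raise ValueError(
            f"vmd={vmd} too large for series of length {len(pair)} (must be < length/10)"
        )


def _lagged(series: np.ndarray, lags, start: int) -> np.ndarray:
    """Columns ``series[t - lag]`` for t in [start, len); one column per lag."""
    n = series.size
    return np.column_stack([series[start - lag : n - lag] for lag in lags])


def compute_ifb(pair: TrajectoryPair, vmd: int, bias_correct: bool = True) -> float:
    """Feedback information (bits/sample): the delayed transfer entropy from
    target to tracking, conditioned on the tracking history.

    Evaluates I(Y_t ; {X_{t-v}, X_{t-v-1}} | {Y_{t-v}, Y_{t-v-1}, Y_{t-1}})
    with v = ``vmd`` over all frames where the lagged copies exist.
    """
    _check_vmd(pair, vmd)
    x, y = pair.target, pair.tracking
    if np.ptp(y) == 0:
        raise DegenerateDataError("tracking series is constant")
    start = vmd + 1
    yt = y[start:]
    xpast = _lagged(x, (vmd, vmd + 1), start)
    ypast = _lagged(y, (vmd, vmd + 1, 1), start)
    return cmi_copula(yt, xpast, ypast, bias_correct=bias_correct).value


def compute_itotal(pair: TrajectoryPair, vmd: int, bias_correct: bool = True) -> float:
    """Total shared information (bits/sample):
    I(Y_t ; {X_t, X_{t-1}, X_{t-v}, X_{t-v-1}})."""
    _check_vmd(pair, vmd)
    x, y = pair.target, pair.tracking
    if np.ptp(y) == 0:
        raise DegenerateDataError("tracking series is constant")
    start = vmd + 1
    yt = y[start:]
    xlags = _lagged(x, (0, 1, vmd, vmd + 1), start)
    return mi_copula(xlags, yt, bias_correct=bias_correct).value


def compute_iff(pair: TrajectoryPair, vmd: int, bias_correct: bool = True) -> float:
    """Feedforward information (bits/sample): Itotal - IFB."""
    return compute_itotal(pair, vmd, bias_correct) - compute_ifb(pair, vmd, bias_correct)


def decompose(pair: TrajectoryPair, vmd: int, bias_correct: bool = True) -> InfoDecomposition:
    """Full decomposition at a given VMD; IFF = Itotal - IFB holds exactly."""
    ifb = compute_ifb(pair, vmd, bias_correct)
    itotal = compute_itotal(pair, vmd, bias_correct)
    return InfoDecomposition(
        ifb=ifb,
        itotal=itotal,
        iff=itotal - ifb,
        vmd=vmd,
        ifb_per_second=rate_per_second(ifb, pair.frame_rate),
    )


def te_latency_curve(
    pair: TrajectoryPair,
    d_min: int = 2,
    d_max: int = 30,
    n_surrogates: int = 0,
    seed: int | None = None,
    bias_correct: bool = True,
) -> TELatencyCurve:
    """Transfer entropy as a function of candidate delay d in [d_min, d_max].

    Each point evaluates the feedback measure at that delay; the peak delay
    (smallest d on exact ties) estimates the VMD.  When ``n_surrogates`` > 0,
    circular-shift surrogates of the target provide a null SE, and the peak is
    flagged low-confidence if it is not at least 3 SEs above the curve median.
    """
    if d_min < 2 or d_min >= d_max:
        raise ValueError(f"need 2 <= d_min < d_max, got [{d_min}, {d_max}]")
    if d_max >= len(pair) / 10:
        raise ValueError(f"d_max={d_max} too large for series of length {len(pair)}")
    delays = np.arange(d_min, d_max + 1)
    te = np.array([compute_ifb(pair, int(d), bias_correct) for d in delays])
    ipeak = int(np.argmax(te))  # first occurrence -> smallest delay on ties
    peak_delay, peak_value = int(delays[ipeak]), float(te[ipeak])
    se = low = None
    if n_surrogates > 0:
        rng = np.random.default_rng(seed)
        n = len(pair)
        null = np.empty(n_surrogates)
        for i in range(n_surrogates):
            shift = int(rng.integers(d_max + 2, n - d_max - 2))
            surrogate = TrajectoryPair(
                np.roll(pair.target, shift), pair.tracking, pair.frame_rate
            )
            null[i] = compute_ifb(surrogate, peak_delay, bias_correct)
        se = float(np.std(null, ddof=1))
        low = bool(peak_value < np.median(te) + 3.0 * se)
    return TELatencyCurve(delays, te, peak_delay, peak_value, se, low)


def estimate_vmd(
    trials,
    d_min: int = 2,
    d_max: int = 30,
    n_surrogates: int = 100,
    seed: int | None = 0,
) -> VMDEstimate:
    """Estimate the VMD as the mean of per-trial TE peak latencies.

    Low-confidence trials (peak indistinguishable from the surrogate null) are
    excluded; if every trial is low-confidence the estimate is refused.  With
    a single usable trial the dispersion is reported as 0.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one trial")
    peaks = []
    for i, pair in enumerate(trials):
        curve = te_latency_curve(
            pair, d_min, d_max, n_surrogates=n_surrogates,
            seed=None if seed is None else seed + i,
        )
        if curve.low_confidence:
            warnings.warn(f"trial {i}: TE peak not significant, excluded", stacklevel=2)
            continue
        peaks.append(curve.peak_delay)
    if not peaks:
        raise DegenerateDataError(
            "no trial produced a significant transfer-entropy peak; VMD undefined"
        )
    sd = float(np.std(peaks, ddof=1)) if len(peaks) > 1 else 0.0
    return VMDEstimate(mean=float(np.mean(peaks)), sd=sd, per_trial=tuple(peaks))


def performance_lag(pair: TrajectoryPair, max_lag: int, min_lag: int = 0) -> int:
    """Integer lag (frames) maximizing the cross-correlation between the
    mean-removed target and tracking series; smallest lag on ties.

    A lag of L means the tracking best matches the target shifted L frames
    into the past (tracking trails the target by L frames).
    """
    if max_lag >= len(pair) / 4:
        raise ValueError(f"max_lag={max_lag} must be < length/4 = {len(pair) / 4}")
    if min_lag > max_lag:
        raise ValueError("min_lag must be <= max_lag")
    x = pair.target - pair.target.mean()
    y = pair.tracking - pair.tracking.mean()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("cross-correlation undefined for a constant series")
    lags = np.arange(min_lag, max_lag + 1)
    n = len(pair)
    cc = np.array(
        [np.dot(x[: n - lag] if lag else x, y[lag:]) if lag >= 0
         else np.dot(x[-lag:], y[: n + lag]) for lag in lags]
    )
    return int(lags[int(np.argmax(cc))])


def rate_per_second(ifb: float, frame_rate: float) -> float:
    """Convert a per-sample information value to bits/s."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    return ifb * frame_rate
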