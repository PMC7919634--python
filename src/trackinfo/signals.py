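"""Pre-programmed one-dimensional target trajectories of controllable predictability.

The target of the tracking task is white noise passed through a narrowband
second-order (sinusoidal) filter.  A single gain parameter ``a1`` controls how
much of the driving noise passes through the filter, and hence how predictable
the trajectory is: small ``a1`` gives a nearly pure oscillation, large ``a1``
a broadband, hard-to-predict wander.  Regardless of ``a1`` the autocorrelation
structure of the output is second order, which is what the downstream
information measures rely on.

Two parameterizations of the filter are provided:

``"resonator"`` (default)
    A stable AR(2) resonator with complex poles at radius ``r = 1 - 0.005*a1``
    and angle ``pi/100`` rad/frame (period about 200 frames, i.e. ~3.3 s at
    60 Hz), driven by the innovation ``eps/a1``:

        x[t] = 2 r cos(pi/100) x[t-1] - r^2 x[t-2] + eps[t]/a1

``"printed"``
    The recurrence ``a1 x[t] = eps[t] + a2 x[t-1] + x[t-2]`` with
    ``a2 = -2 a1 cos(pi/100)``, taken literally.  Its characteristic roots
    include one close to ``-2 cos(pi/100)`` for every ``a1 > 0``, so the
    recurrence diverges; generating with it raises :class:`InstabilityError`.
    It is kept available so the behaviour of the literal recurrence can be
    inspected and tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .exceptions import DegenerateDataError, InstabilityError

__all__ = [
    "POLE_ANGLE",
    "BANDWIDTH_PER_A1",
    "DEFAULT_A1_SWEEP",
    "SignalConfig",
    "TargetSignal",
    "ar2_coefficients",
    "stationary_variance_gain",
    "generate_target",
    "autocorrelation_order_check",
]

#: Pole angle of the resonator in radians per frame (oscillation period
#: 2*pi/POLE_ANGLE = 200 frames, ~3.3 s at 60 Hz).
POLE_ANGLE = np.pi / 100.0

#: Distance of the resonator poles from the unit circle per unit of a1:
#: pole radius r = 1 - BANDWIDTH_PER_A1 * a1.  Larger a1 -> broader band ->
#: less predictable trajectory.
BANDWIDTH_PER_A1 = 0.005

#: Default predictability sweep: four conditions, geometrically spaced so the
#: noise pass-through spans about two orders of magnitude from low to high
#: signal complexity.
DEFAULT_A1_SWEEP = (0.5, 2.0, 8.0, 32.0)

_DIVERGENCE_BOUND = 1e9


@dataclass(frozen=True)
class SignalConfig:
    """Configuration of a generated target trajectory.

    Parameters
    ----------
    a1
        Filter gain (> 0).  Controls the noise pass-through of the filter and
        therefore the predictability of the trajectory: larger values give
        more complex, less predictable signals.
    n_frames
        Total number of frames generated, including burn-in.
    frame_rate
        Display frame rate in Hz.
    burn_in
        Frames discarded at the start to remove the transient of the
        zero-initialized recurrence.
    seed
        Seed of the driving white noise.
    noise_sd
        Standard deviation of the driving white noise ``eps``.  The
        innovation entering the filter is ``eps/a1``.
    variant
        ``"resonator"`` (stable, default) or ``"printed"`` (literal
        recurrence; unstable for all a1).
    """

    a1: float
    n_frames: int = 10_500
    frame_rate: float = 60.0
    burn_in: int = 500
    seed: int | None = None
    noise_sd: float = 1.0
    variant: str = "resonator"

    def __post_init__(self) -> None:
        if not self.a1 > 0:
            raise ValueError(f"a1 must be positive, got {self.a1}")
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.burn_in < 0 or self.n_frames <= self.burn_in:
            raise ValueError(
                f"need n_frames > burn_in >= 0, got n_frames={self.n_frames}, "
                f"burn_in={self.burn_in}"
            )
        if self.variant not in ("resonator", "printed"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class TargetSignal:
    """A generated target trajectory (screen units, one value per frame)."""

    positions: np.ndarray
    config: SignalConfig

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))

    def __len__(self) -> int:
        return self.positions.size


def ar2_coefficients(a1: float, variant: str = "resonator") -> tuple[float, float]:
    """AR(2) coefficients (phi1, phi2) of ``x[t] = phi1 x[t-1] + phi2 x[t-2] + innov``.

    For the resonator variant the poles are ``r exp(+-i*POLE_ANGLE)`` with
    ``r = 1 - BANDWIDTH_PER_A1*a1``; for the printed variant the coefficients
    follow from dividing the literal recurrence by a1.
    """
    if variant == "resonator":
        r = 1.0 - BANDWIDTH_PER_A1 * a1
        if not 0.0 < r < 1.0:
            raise InstabilityError(
                f"a1={a1} puts the resonator pole radius at {r}, outside (0, 1)"
            )
        return 2.0 * r * np.cos(POLE_ANGLE), -(r**2)
    if variant == "printed":
        a2 = -2.0 * a1 * np.cos(POLE_ANGLE)
        return a2 / a1, 1.0 / a1
    raise ValueError(f"unknown variant {variant!r}")


def stationary_variance_gain(a1: float, variant: str = "resonator") -> float:
    """Ratio Var(x)/Var(innovation) of the stationary AR(2) output.

    Uses the closed form ``(1-phi2) / ((1+phi2) ((1-phi2)^2 - phi1^2))``.
    Raises :class:`InstabilityError` if the parameterization is not stationary.
    """
    phi1, phi2 = ar2_coefficients(a1, variant)
    denom = (1.0 + phi2) * ((1.0 - phi2) ** 2 - phi1**2)
    if denom <= 0:
        raise InstabilityError(f"a1={a1} ({variant}) is not a stationary AR(2)")
    return (1.0 - phi2) / denom


def generate_target(config: SignalConfig) -> TargetSignal:
    """Generate a target trajectory from ``config``.

    The recurrence is initialized at zero (x[0] = x[1] = 0) and driven by
    seeded Gaussian white noise; the first ``burn_in`` frames are discarded.
    Deterministic given the seed.

    Raises
    ------
    InstabilityError
        If the recurrence diverges (always the case for the literal
        ``"printed"`` variant).
    """
    rng = np.random.default_rng(config.seed)
    eps = rng.normal(0.0, config.noise_sd, size=config.n_frames)
    phi1, phi2 = ar2_coefficients(config.a1, config.variant)
    # x[t] - phi1 x[t-1] - phi2 x[t-2] = eps[t]/a1, zero initial conditions
    with np.errstate(over="ignore", invalid="ignore"):
        x = _sig.lfilter([1.0 / config.a1], [1.0, -phi1, -phi2], eps)
    if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > _DIVERGENCE_BOUND * max(
        config.noise_sd, 1.0
    ):
        raise InstabilityError(
            f"target recurrence diverged for a1={config.a1} "
            f"(variant={config.variant!r}); the literal printed recurrence is "
            f"unstable for every a1 — use variant='resonator'"
        )
    return TargetSignal(positions=x[config.burn_in :], config=config)


def autocorrelation_order_check(signal, max_lag: int) -> np.ndarray:
    """Partial autocorrelations of the trajectory at lags ``1..max_lag``.

    A correctly generated target has second-order autocorrelation: PACF values
    at lags >= 3 should be statistically indistinguishable from zero
    (roughly within ``2/sqrt(N)``).

    Parameters
    ----------
    signal
        A :class:`TargetSignal` or a plain 1-d sequence.
    max_lag
        Largest lag; must be well below the series length.
    """
    x = signal.positions if isinstance(signal, TargetSignal) else np.asarray(signal, float)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if max_lag >= x.size:
        raise ValueError(f"max_lag={max_lag} must be smaller than series length {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("partial autocorrelation undefined for a constant series")
    from statsmodels.tsa.stattools import pacf

    vals = pacf(x, nlags=max_lag, method="yw")
    return vals[1:]
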