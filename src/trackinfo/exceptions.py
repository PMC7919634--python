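"""Exception types shared across trackinfo modules."""


class TrackinfoError(Exception):
    """Base class for all trackinfo errors."""


class InstabilityError(TrackinfoError, RuntimeError):
    """A recurrence or closed-loop simulation diverged beyond its magnitude bound."""


class DegenerateDataError(TrackinfoError, ValueError):
    """Input data are degenerate for the requested estimator.

    Raised for constant columns, perfectly dependent inputs (singular joint
    covariance), non-finite samples, and similar cases where the rank-based
    Gaussian-copula machinery is undefined.
    """
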