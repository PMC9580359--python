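"""Exception hierarchy for tfbcsp.

Every error raised on bad input derives from :class:`TfbcspError` so callers
can catch library failures without masking programming errors.
"""


class TfbcspError(Exception):
    """Base class for all tfbcsp errors."""


class InvalidParameterError(TfbcspError, ValueError):
    """A parameter violates its contract (e.g. band edges vs. Nyquist)."""


class InvalidDataError(TfbcspError, ValueError):
    """Input data violate an invariant (non-finite samples, bad shapes)."""


class OutOfRangeError(TfbcspError, ValueError):
    """A requested window lies outside the epoch extent."""


class InvalidGridError(TfbcspError, ValueError):
    """Grid parameters do not tile the requested range exactly."""


class InvalidLabelsError(TfbcspError, ValueError):
    """Labels are missing a class or contain more than two classes."""


class DegenerateTrialError(TfbcspError, ValueError):
    """A trial carries no usable signal (zero trace / zero variance)."""


class ContractError(TfbcspError, ValueError):
    """A caller-supplied component broke its contract (e.g. an evaluator
    returning an accuracy outside [0, 1], or mismatched dimensions)."""


class StratificationError(TfbcspError, ValueError):
    """A cross-validation fold would not contain both classes."""


class LeakageError(TfbcspError, RuntimeError):
    """A fitting routine was handed data fingerprinted as held-out."""
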