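"""Exception hierarchy for twostay.

All errors raised by the package derive from :class:`TwostayError` so callers
can catch the package's failures with a single clause while still seeing
``ValueError`` semantics where that is the natural builtin.
"""


class TwostayError(Exception):
    """Base class for all twostay errors."""


class InvalidPairError(TwostayError, ValueError):
    """A prediction pair violates its invariants (lengths, emptiness, sign)."""


class LossDomainError(TwostayError, ValueError):
    """A loss was evaluated outside its domain (e.g. MRE with a zero outcome)."""


class UnsupportedTransformError(TwostayError, ValueError):
    """Requested an operation a transform does not support (e.g. inverting truncation)."""


class DegenerateTargetError(TwostayError, ValueError):
    """The training target is degenerate for the requested task (single class)."""


class SchemaMismatchError(TwostayError, ValueError):
    """Prediction-time columns do not match the columns seen at fit time."""

    def __init__(self, missing=(), extra=()):
        self.missing = list(missing)
        self.extra = list(extra)
        super().__init__(
            f"feature columns do not match training schema: "
            f"missing={self.missing!r}, extra={self.extra!r}"
        )


class InfeasibleCutoffError(TwostayError, ValueError):
    """No probability cutoff attains the requested sensitivity target."""

    def __init__(self, target, best_attainable):
        self.target = target
        self.best_attainable = best_attainable
        super().__init__(
            f"no cutoff attains the sensitivity target {target}; "
            f"best attainable is {best_attainable}"
        )


class UnfittableStageError(TwostayError, ValueError):
    """A stage of the two-stage model has no usable training data."""


class UndefinedMetricError(TwostayError, ValueError):
    """A metric is undefined on the given inputs (e.g. constant predictions)."""
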