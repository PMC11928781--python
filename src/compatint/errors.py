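"""Exception and warning types shared across the package."""


class CompatIntError(ValueError):
    """Base class for all validation errors raised by compatint."""


class InvalidEstimateError(CompatIntError):
    """A ratio estimate violates its invariants (bounds, ordering, positivity)."""


class InvalidLevelError(CompatIntError):
    """A confidence level or alpha lies outside the open interval (0, 1)."""


class InvalidNullError(CompatIntError):
    """A null value on the ratio scale is not strictly positive."""


class InvalidGridError(CompatIntError):
    """A consonance-curve grid is empty, non-positive or not strictly increasing."""


class InvalidMarginError(CompatIntError):
    """A non-inferiority margin is not strictly positive."""


class MissingBoundError(CompatIntError):
    """Equivalence testing requires both a lower and an upper margin."""


class MissingTruthError(CompatIntError):
    """An operation needs per-entry truth labels that the p-value set lacks."""


class InvalidPValueError(CompatIntError):
    """A p-value lies outside [0, 1], or p = 0 where a finite z is required."""


class OutOfRangeError(CompatIntError):
    """A requested inverse lies outside the range of the forward map."""


class NoEvidenceError(CompatIntError):
    """Margin derivation was asked to pool an empty list of reference estimates."""


class InvalidSpecError(CompatIntError):
    """A simulation specification violates its invariants (n >= 1, sd > 0)."""


class TableFormatError(CompatIntError):
    """A delimited input table has a malformed header or schema."""


class AsymmetryWarning(UserWarning):
    """The reported CI is not log-symmetric around the point estimate.

    Emitted when |ln(point) - midpoint of the log-scale CI| exceeds 0.01 * se.
    Profile-likelihood or heavily rounded intervals trigger this; derived
    quantities then rest on an approximation the input does not quite satisfy.
    """
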