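"""Exception hierarchy for poissonplus.

All errors raised by the library derive from :class:`PoissonPlusError` so
callers (and the CLI) can distinguish validation problems from numerical
failures with a single except clause.
"""


class PoissonPlusError(Exception):
    """Base class for all poissonplus errors."""


class InvalidInputError(PoissonPlusError, ValueError):
    """An argument violates a precondition (wrong range, empty vector, ...)."""


class SaturatedChipError(PoissonPlusError):
    """Every partition is positive: the concentration has no finite estimate."""


class BelowValidityLimitError(PoissonPlusError):
    """P(neg) lies below the closed-form model's theoretical validity limit.

    The closed-form (approximation) estimator has a real solution only for
    P(neg) >= exp(-0.5 * (v0/sigma)^2); below that the discriminant is
    negative and the result would be imaginary.
    """


class NumericalError(PoissonPlusError):
    """Root finding or another numerical procedure failed to converge."""


class CalibrationError(PoissonPlusError):
    """A chip cannot be calibrated (empty population, degenerate fit, ...)."""
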