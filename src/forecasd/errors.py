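"""Exception hierarchy used across the package.

Every error raised deliberately by forecasd derives from :class:`ForecasdError`,
so callers can catch one base class at pipeline boundaries.
"""


class ForecasdError(Exception):
    """Base class for all forecasd errors."""


class FormatError(ForecasdError):
    """A file or field does not match the expected text format."""


class MissingColumnError(FormatError):
    """A required column is absent from a tabular input."""


class DimensionMismatchError(FormatError):
    """Matrix dimensions disagree with the accompanying metadata."""


class DuplicateGeneError(FormatError):
    """A gene identifier occurs more than once where uniqueness is required."""


class ValidationError(ForecasdError):
    """An in-memory object violates a type invariant or precondition."""


class DegenerateInputError(ForecasdError):
    """An analysis input is degenerate (empty class, all-tied values, ...)."""


class SeparationError(ForecasdError):
    """Logistic fit failed due to perfect or quasi-perfect separation."""


class CollinearityError(ForecasdError):
    """Design matrix is rank-deficient or numerically collinear."""
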