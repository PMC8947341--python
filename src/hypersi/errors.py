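"""Exception hierarchy for the processing pipeline.

All errors derive from :class:`HyperSiError` so batch drivers can catch one
type; most also derive from the closest builtin (``ValueError``/``OSError``)
so library users relying on standard idioms are not surprised.
"""


class HyperSiError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HyperSiError, ValueError):
    """A file does not conform to its declared on-disk format."""


class TruncationError(FormatError):
    """A binary payload is shorter or longer than its header declares."""


class SchemaError(HyperSiError, ValueError):
    """A tabular input is missing required columns or sheets."""


class ValidationError(HyperSiError, ValueError):
    """A value violates a domain invariant (cohort name, empty ROI, ...)."""


class UndefinedStatisticError(HyperSiError, ArithmeticError):
    """A requested statistic is undefined for the given data (zero variance)."""


class RegistrationError(HyperSiError, ValueError):
    """Two images cannot be fused because their grids do not match."""
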