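"""Exception types raised by the pipeline.

All errors derive from :class:`PeriplaqueError` so callers can catch the
package's failures with a single except clause.
"""


class PeriplaqueError(Exception):
    """Base class for all periplaque errors."""


class ValidationError(PeriplaqueError, ValueError):
    """An input violates a documented precondition (shape, sign, schema)."""


class CalibrationError(PeriplaqueError):
    """Physical pixel size is missing and no override was supplied."""


class FormatError(PeriplaqueError):
    """A file's layout does not match the declared channel map."""


class PlacementError(PeriplaqueError):
    """A synthetic object could not be placed without overlap."""


class UndefinedRatioError(PeriplaqueError):
    """A normalizing denominator (field or parenchyma mean) is zero."""


class InsufficientDataError(PeriplaqueError):
    """A statistical comparison was requested with too few observations."""
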