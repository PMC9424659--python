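"""Exception hierarchy.

All domain errors derive from :class:`DomainError` (a ``ValueError``), so callers
can catch one type for any precondition violation.
"""


class DomainError(ValueError):
    """Invalid input for a domain operation (non-positive size, bad band, ...)."""


class UnsupportedPopulationError(DomainError):
    """Subject falls outside the supported populations (e.g. age < 1 year)."""


class CalibrationError(DomainError):
    """Inconsistent calibration reference (e.g. total clearance below renal)."""


class PopulationMismatchError(DomainError):
    """A clearance model was combined with a subject from another population."""


class InsufficientSamplingError(DomainError):
    """Observations do not span the dosing interval needed for recovery."""
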