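"""Typed exceptions raised at the package boundary.

All validation failures raise one of these; readers never silently coerce
malformed input.
"""


class BonequalError(Exception):
    """Base class for all bonequal errors."""


class FormatError(BonequalError):
    """A file does not conform to the documented dialect (missing columns,
    mismatched slice shapes, unreadable content)."""


class ValidationError(BonequalError):
    """Structurally readable data violates a domain invariant (negative load,
    non-monotone time, decreasing crack lengths, empty mask, ...)."""


class DomainError(BonequalError):
    """An argument lies outside the mathematical domain of an operation
    (a/W outside (0, 1), a >= W, region outside the spectral axis)."""


class CalibrationError(BonequalError):
    """Calibration standards are inconsistent (equal or swapped gray values)."""


class FitFlag(BonequalError):
    """A model fit failed to converge or produced out-of-range parameters;
    the offending result is flagged rather than silently reported."""
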