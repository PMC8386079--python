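"""Exception hierarchy shared across the package."""


class DCapError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DCapError):
    """An input file could not be parsed."""


class ValidationError(DCapError):
    """Parsed data violates a structural invariant (negative counts,
    duplicated identifiers, shape mismatches, ...)."""


class MissingGroupError(DCapError):
    """A (subject, cell type) group required by an operation is absent."""


class DegenerateGroupError(DCapError):
    """A group or fit carries no usable signal (all-zero counts, all-zero
    coefficients)."""
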