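"""Exception hierarchy for the HPTLC identification toolkit."""


class HptlcError(Exception):
    """Base class for all package errors."""


class AchromaticColourError(HptlcError):
    """Raised for grey pixels (R = G = B), which carry no hue."""


class SchemaError(HptlcError):
    """A library file is missing required columns."""


class LibraryValidationError(HptlcError):
    """A library row violates a field invariant (range, uniqueness, ...)."""


class SpectrumError(HptlcError):
    """Malformed spectrum data or an operation on a degenerate spectrum."""


class WindowError(SpectrumError):
    """A comparison window does not sufficiently overlap the sampled range."""


class CascadeError(HptlcError):
    """The filter cascade cannot run (missing Rf, empty view, bad label)."""
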