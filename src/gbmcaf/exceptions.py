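"""Exception hierarchy.

All package errors derive from :class:`GbmCafError` so callers can catch one
type at pipeline boundaries while tests discriminate the specific failure.
"""


class GbmCafError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(GbmCafError):
    """Invalid simulation or pipeline configuration (bad fractions, unknown labels...)."""


class FormatError(GbmCafError):
    """Malformed input file: dimension mismatch, non-integer counts, missing columns."""


class ParameterError(GbmCafError):
    """Parameter outside its valid domain (non-positive bandwidth, bad quantile...)."""


class PanelError(GbmCafError):
    """Marker panel unusable on the given matrix (no panel gene present)."""


class GeneLookupError(GbmCafError):
    """A required gene is absent from the matrix."""
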