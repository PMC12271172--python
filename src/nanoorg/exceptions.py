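"""Exception hierarchy for nanoorg.

All errors raised by the library derive from :class:`NanoorgError` so callers
can catch pipeline failures with a single except clause.
"""


class NanoorgError(Exception):
    """Base class for all nanoorg errors."""


class SchemaError(NanoorgError):
    """An input table is missing a required column."""


class ParseError(NanoorgError):
    """A value in an input file could not be parsed."""


class ParameterError(NanoorgError, ValueError):
    """An operation was called with an invalid parameter value."""


class GeometryError(NanoorgError):
    """Inconsistent geometry: shape mismatch, invalid polygon, out-of-frame ROI."""


class DegeneracyError(NanoorgError):
    """A fit is underdetermined (e.g. collinear beads for an affine model)."""


class PackingError(NanoorgError):
    """Synthetic synapses could not be placed without overlap."""


class UndefinedDensityError(NanoorgError):
    """A density is requested over a zero-area region."""


class UndefinedEnrichmentError(NanoorgError):
    """Enrichment index requested with no reference SSD peaks."""


class DegenerateBleachError(NanoorgError):
    """FRAP normalization with no bleach depth (F_i == F_0)."""


class NormalizationError(NanoorgError):
    """Per-culture vehicle normalization is impossible (no vehicle rows)."""


class InsufficientDataError(NanoorgError):
    """Too few observations for the requested statistical operation."""
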