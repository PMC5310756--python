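"""Exception hierarchy.

All package errors derive from :class:`DynasigError` so callers can catch
one base class; most also derive from ``ValueError`` because they signal
invalid inputs rather than internal failures.
"""


class DynasigError(Exception):
    """Base class for all dynasig errors."""


class ParameterError(DynasigError, ValueError):
    """A parameter is outside its valid domain (e.g. logistic r > 4)."""


class LengthError(DynasigError, ValueError):
    """A series is too short for the requested operation."""


class FormatError(DynasigError, ValueError):
    """A series table violates the expected CSV layout."""


class GapError(FormatError):
    """Years are not contiguous; interpolation is never done silently."""


class DegenerateSeriesError(DynasigError, ValueError):
    """A constant (zero-variance) series cannot be standardized."""


class ProvenanceError(DynasigError, TypeError):
    """A prepared series was passed where a raw series is required."""


class EmbeddingError(LengthError):
    """The series cannot support the requested (E, tau, tp) embedding."""


class NeighborCountError(DynasigError, ValueError):
    """Fewer than E + 1 candidate neighbors are available."""


class DegenerateGeometryError(DynasigError, ValueError):
    """All library points coincide with the predictee (mean distance 0)."""


class SampleSizeError(DynasigError, ValueError):
    """Too few prediction pairs for the requested statistic."""
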