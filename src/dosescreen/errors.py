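"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`DoseScreenError`, so callers (and the CLI) can distinguish
validation, geometry, format and computation problems from bugs.
"""


class DoseScreenError(Exception):
    """Base class for all package errors."""


class GeometryError(DoseScreenError):
    """Grids or masks whose geometries are incompatible, or no spatial overlap."""


class FormatError(DoseScreenError):
    """A file does not conform to the expected format (missing DICOM attribute,
    corrupted fixture payload, schema violation)."""


class VersionError(FormatError):
    """Fixture written by an incompatible schema version."""


class DomainError(DoseScreenError):
    """An argument outside the mathematical domain of an operation
    (empty mask, point outside the grid, non-positive denominator)."""


class ConfigurationError(DoseScreenError):
    """Inconsistent analysis configuration (missing criterion, mask or limit)."""


class CohortError(DoseScreenError):
    """A cohort too small or inconsistent for the requested statistic."""


class GenerationError(DoseScreenError):
    """Synthetic-case generation could not satisfy its constraints."""


class SizeError(DoseScreenError):
    """An input larger than an operation's guard allows (brute-force oracle)."""
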