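"""Exception hierarchy shared across the package."""


class FirescapeError(Exception):
    """Base class for all package errors."""


class AlignmentError(FirescapeError):
    """Raster geometries are incompatible (mismatched grid or ratio)."""


class CoverageError(FirescapeError):
    """Source raster does not cover the target extent."""


class KindError(FirescapeError):
    """Raster kind (continuous/categorical/binary) unsuitable for an operation."""


class DomainError(FirescapeError):
    """Values outside the operation's admissible domain."""


class SizeError(FirescapeError):
    """Grid too small for the requested stencil."""


class NoSourceError(FirescapeError):
    """Distance transform requested on a mask without source cells."""


class DegenerateStratumError(FirescapeError):
    """A stratum has no fire cells (or no cells at all)."""


class ClassificationError(FirescapeError):
    """All values fall outside the classing breakpoints."""


class ConsistencyError(FirescapeError):
    """A class observed in a raster has no frequency-ratio row."""


class MatchingError(FirescapeError):
    """Matching preconditions violated (no controls, all excluded, ...)."""
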