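"""Exception hierarchy shared across the package.

``KoehlerError`` is the common base; ``ValidationError`` subclasses signal
bad user inputs (CLI exit code 2) while I/O problems surface as the
standard ``OSError`` family (exit code 3).
"""

from __future__ import annotations

__all__ = [
    "KoehlerError",
    "ValidationError",
    "ColinearPointsError",
    "OutOfBoundsError",
    "DuplicatePointError",
    "NoWhiteAreaError",
    "GrayscaleInputError",
]


class KoehlerError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(KoehlerError, ValueError):
    """Invalid user-supplied parameter or input."""


class ColinearPointsError(ValidationError):
    """Three of the four source points are (nearly) colinear."""


class OutOfBoundsError(ValidationError):
    """A source point lies outside the image."""


class DuplicatePointError(ValidationError):
    """Two source points coincide."""


class NoWhiteAreaError(ValidationError):
    """No pixel reaches the white threshold; auto-selection impossible."""


class GrayscaleInputError(ValidationError):
    """Input image has no color channels; the method needs RGB."""
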