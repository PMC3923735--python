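"""End-to-end conveniences tying the modules together on RGB images."""

from __future__ import annotations

import numpy as np

from . import colorspace
from .enhancement import EnhancementSettings, enhance_nuclei
from .illumination import (
    CorrectionSettings,
    SourcePoint,
    SourcePointSet,
    apply_correction,
    auto_select_points,
    build_mask,
    validate_points,
)

__all__ = ["correct_rgb", "sharpen_rgb", "points_from_rgb"]


def points_from_rgb(
    rgb: np.ndarray,
    coords: list[tuple[float, float]] | None = None,
    reference: float = 100.0,
    white_threshold: float = 90.0,
) -> SourcePointSet:
    """Build a source-point set from pixel coordinates, or auto-select one.

    With explicit ``coords`` (four ``(x, y)`` pairs) the observed L* at
    each pixel is read off the image; without, the quadrant heuristic
    picks probable-white points."""
    lab = colorspace.rgb_to_lab(rgb)
    if coords is None:
        return auto_select_points(lab, white_threshold=white_threshold, reference=reference)
    pts = SourcePointSet(
        tuple(
            SourcePoint(float(x), float(y), float(lab[int(round(y)), int(round(x)), 0]))
            for x, y in coords
        ),
        reference=reference,
    )
    return validate_points(pts, lab.shape[:2])


def correct_rgb(
    rgb: np.ndarray,
    points: SourcePointSet | None = None,
    factor: int = 5,
    reference: float = 100.0,
    white_threshold: float = 90.0,
) -> tuple[np.ndarray, np.ndarray, SourcePointSet]:
    """Correct uneven illumination on an RGB image.

    Converts to LAB, estimates the deficit mask from the given (or
    auto-selected) source points, restores ``factor/5`` of it to L*, and
    converts back.  Returns ``(corrected_rgb, mask, points_used)``; the
    returned RGB is unclamped floats, clamp on write-out.
    """
    lab = colorspace.rgb_to_lab(rgb)
    if points is None:
        points = auto_select_points(lab, white_threshold=white_threshold, reference=reference)
    mask = build_mask(points, lab.shape[:2])
    corrected = apply_correction(lab, mask, CorrectionSettings(factor=factor, reference=reference))
    return colorspace.lab_to_rgb(corrected), mask, points


def sharpen_rgb(rgb: np.ndarray, settings: EnhancementSettings | None = None) -> np.ndarray:
    """Apply the b*-gated unsharp mask to an RGB image (via LAB and back)."""
    lab = colorspace.rgb_to_lab(rgb)
    return colorspace.lab_to_rgb(enhance_nuclei(lab, settings))
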