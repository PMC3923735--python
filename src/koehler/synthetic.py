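"""Synthetic H&E phantoms with known ground-truth illumination fields.

A phantom mimics the gross appearance of an H&E-stained section: a white
unstained background, pinkish elliptical cytoplasm regions (eosin,
``b* > 0``) each carrying a smaller bluish elliptical nucleus
(hematoxylin, ``b* < 0``).  A known additive L* field — planar, mildly
quadratic, or uniform, always ≤ 0 (darkening) — degrades the clean image,
and a boolean map records which pixels are truly unstained white.  Every
correction stage can then be scored against exact ground truth.

Defaults model the documented artifact: a planar lightness loss growing to
roughly 9 L* units across a 256×256 field, mild enough that unstained
pixels stay above the L* ≥ 90 white-detection threshold everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.draw import ellipse

from . import colorspace
from .errors import ValidationError
from .imgio import from_uint8, to_uint8

__all__ = ["FieldSpec", "Phantom", "RecoveryReport", "generate_phantom", "measure_recovery"]

#: Jittered base colors (8-bit RGB): eosin-pink cytoplasm, hematoxylin-blue
#: nuclei.  Chosen so that under this package's linear RGB→LAB conversion
#: cytoplasm keeps b* > 0 and nuclei keep b* < 0 across the full jitter
#: range, and cytoplasm stays below the L* = 90 white threshold.
CYTOPLASM_RGB = (240, 150, 140)
NUCLEUS_RGB = (70, 85, 160)
_JITTER = 10  # uniform per-object color jitter, 8-bit counts


@dataclass(frozen=True)
class FieldSpec:
    """Additive L* illumination field.

    ``planar``: offset + alpha·x + beta·y; ``quadratic`` adds the
    second-order terms; ``uniform``: offset only.  Values must stay in
    [−100, 0] over the image — the field darkens, never brightens.
    """

    kind: str = "planar"
    alpha: float = -0.02   # L* per pixel in x
    beta: float = -0.015   # L* per pixel in y
    offset: float = 0.0
    axx: float = 0.0
    ayy: float = 0.0
    axy: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("planar", "quadratic", "uniform"):
            raise ValidationError(f"unknown field kind {self.kind!r}")

    def evaluate(self, height: int, width: int) -> np.ndarray:
        """The field sampled on the pixel grid, validated to [−100, 0]."""
        x = np.arange(width, dtype=float)[None, :]
        y = np.arange(height, dtype=float)[:, None]
        if self.kind == "uniform":
            f = np.full((height, width), self.offset)
        else:
            f = self.offset + self.alpha * x + self.beta * y
            if self.kind == "quadratic":
                f = f + self.axx * x**2 + self.ayy * y**2 + self.axy * x * y
        if f.max() > 1e-9 or f.min() < -100.0:
            raise ValidationError(
                "illumination field must lie in [-100, 0] over the image "
                f"(got range [{f.min():.3g}, {f.max():.3g}])"
            )
        return f


@dataclass(frozen=True)
class Phantom:
    clean: np.ndarray      # (H, W, 3) float RGB in [0, 1], 8-bit quantized
    degraded: np.ndarray   # clean with the field added to L*, re-quantized
    field: np.ndarray      # (H, W) additive L* field, <= 0
    white_map: np.ndarray  # (H, W) bool, truly unstained pixels
    seed: int


@dataclass(frozen=True)
class RecoveryReport:
    white_rmse: float      # L* RMSE vs clean over the white map
    overall_rmse: float    # L* RMSE vs clean over all pixels
    max_delta_a: float     # max |a* change| vs the degraded image
    max_delta_b: float     # max |b* change| vs the degraded image


def generate_phantom(
    height: int = 256,
    width: int = 256,
    n_nuclei: int = 30,
    seed: int = 0,
    field: FieldSpec | None = None,
) -> Phantom:
    """Draw an H&E-like phantom and degrade it with a known L* field.

    Deterministic for a given argument tuple.  Four corner patches (one per
    quadrant) are kept clear of tissue so the white map is never empty in
    any quadrant, and at least 5 % of all pixels must remain white.

    Raises
    ------
    ValidationError
        If the image is too small (< 16 px a side) or too crowded to place
        the requested objects while keeping the white-area guarantees.
    """
    if height < 16 or width < 16:
        raise ValidationError("phantom images must be at least 16x16")
    if n_nuclei < 0:
        raise ValidationError("n_nuclei must be non-negative")
    field = field or FieldSpec()
    rng = np.random.default_rng(seed)

    img = np.ones((height, width, 3))
    painted = np.zeros((height, width), dtype=bool)

    # reserved white patch in each quadrant corner
    s = max(3, min(height, width) // 16)
    reserved = [
        (0, s, 0, s),
        (0, s, width - s, width),
        (height - s, height, 0, s),
        (height - s, height, width - s, width),
    ]

    def hits_reserved(cy: float, cx: float, r: float) -> bool:
        return any(
            cy + r >= r0 and cy - r < r1 and cx + r >= c0 and cx - r < c1
            for r0, r1, c0, c1 in reserved
        )

    min_dim = min(height, width)
    placed = 0
    attempts = 0
    max_attempts = max(200, 60 * n_nuclei)
    while placed < n_nuclei:
        if attempts >= max_attempts:
            raise ValidationError(
                f"could not place {n_nuclei} tissue regions in a "
                f"{width}x{height} image without exhausting the white area"
            )
        attempts += 1
        r_cyt = rng.uniform(0.03, 0.07) * min_dim
        cy = rng.uniform(r_cyt, height - 1 - r_cyt)
        cx = rng.uniform(r_cyt, width - 1 - r_cyt)
        rot = rng.uniform(0.0, np.pi)
        ecc = rng.uniform(0.55, 0.95)
        if hits_reserved(cy, cx, r_cyt):
            continue
        cyt_color = (np.array(CYTOPLASM_RGB) + rng.uniform(-_JITTER, _JITTER, 3)) / 255.0
        nuc_color = (np.array(NUCLEUS_RGB) + rng.uniform(-_JITTER, _JITTER, 3)) / 255.0
        rr, cc = ellipse(cy, cx, r_cyt, ecc * r_cyt, shape=(height, width), rotation=rot)
        img[rr, cc] = np.clip(cyt_color, 0.0, 1.0)
        painted[rr, cc] = True
        r_nuc = rng.uniform(0.4, 0.6) * r_cyt
        rr, cc = ellipse(cy, cx, r_nuc, ecc * r_nuc, shape=(height, width), rotation=rot)
        img[rr, cc] = np.clip(nuc_color, 0.0, 1.0)
        placed += 1

    white_map = ~painted
    if white_map.mean() < 0.05:
        raise ValidationError("less than 5% of the phantom remained white")

    clean = from_uint8(to_uint8(img))
    f = field.evaluate(height, width)
    lab = colorspace.rgb_to_lab(clean)
    lab[..., 0] = np.clip(lab[..., 0] + f, 0.0, 100.0)
    degraded = from_uint8(to_uint8(colorspace.lab_to_rgb(lab)))
    return Phantom(clean=clean, degraded=degraded, field=f, white_map=white_map, seed=seed)


def measure_recovery(phantom: Phantom, corrected: np.ndarray) -> RecoveryReport:
    """Score a corrected RGB image against the phantom's ground truth.

    Lightness RMSEs are taken against the *clean* image (over the white
    map and over all pixels); chromaticity deltas are taken against the
    *degraded* image, since a faithful correction must not move a*/b*.
    """
    corrected = np.asarray(corrected, dtype=float)
    if corrected.shape != phantom.clean.shape:
        raise ValidationError(
            f"corrected shape {corrected.shape} != phantom shape {phantom.clean.shape}"
        )
    lab_clean = colorspace.rgb_to_lab(phantom.clean)
    lab_degr = colorspace.rgb_to_lab(phantom.degraded)
    lab_corr = colorspace.rgb_to_lab(corrected)
    dL = lab_corr[..., 0] - lab_clean[..., 0]
    return RecoveryReport(
        white_rmse=float(np.sqrt(np.mean(dL[phantom.white_map] ** 2))),
        overall_rmse=float(np.sqrt(np.mean(dL**2))),
        max_delta_a=float(np.abs(lab_corr[..., 1] - lab_degr[..., 1]).max()),
        max_delta_b=float(np.abs(lab_corr[..., 2] - lab_degr[..., 2]).max()),
    )
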