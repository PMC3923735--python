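"""Nuclei-selective unsharp masking on the L* channel.

Hematoxylin stains nuclei blue, and bluish pixels sit at ``b* < 0`` in CIE
LAB.  The enhancement blurs the L* plane with a small Gaussian kernel,
takes the detail (original minus blurred, clamped to the 0–100 lightness
range), and adds ``factor × detail`` back — but only at pixels whose b* is
negative, so eosin-stained cytoplasm and background are left untouched.
The chromaticity planes are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError

__all__ = ["EnhancementSettings", "gaussian_kernel", "blur_lightness", "enhance_nuclei"]


@dataclass(frozen=True)
class EnhancementSettings:
    """Sharpening strength ``factor`` (integer 1..12), Gaussian ``sigma``
    (default 3), odd ``kernel_size`` (default 3) and the detail
    ``threshold`` (default 0, i.e. every detail counts)."""

    factor: int = 6
    sigma: float = 3.0
    kernel_size: int = 3
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= int(self.factor) <= 12) or int(self.factor) != self.factor:
            raise ValidationError(
                f"enhancement factor must be an integer in [1, 12], got {self.factor}"
            )
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValidationError(f"kernel size must be odd and >= 3, got {self.kernel_size}")
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be positive, got {self.sigma}")
        if self.threshold < 0:
            raise ValidationError(f"threshold must be non-negative, got {self.threshold}")


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Normalized Gaussian weights sampled at integer offsets.

    ``G(x, y) = exp(-(x² + y²) / (2σ²)) / (2πσ²)`` evaluated on the
    ``size × size`` grid centered at the origin, then rescaled to sum to 1
    (the normalization absorbs the ``1/(2πσ²)`` prefactor).
    """
    if size % 2 == 0 or size < 1:
        raise ValidationError(f"kernel size must be odd, got {size}")
    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    off = np.arange(size, dtype=float) - size // 2
    g = np.exp(-(off[:, None] ** 2 + off[None, :] ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def blur_lightness(lab: np.ndarray, settings: EnhancementSettings | None = None) -> np.ndarray:
    """Gaussian low-pass of the L* plane, clamped to [0, 100].

    Borders are handled by edge replication to avoid rim artifacts.
    """
    settings = settings or EnhancementSettings()
    lab = np.asarray(lab, dtype=float)
    kernel = gaussian_kernel(settings.kernel_size, settings.sigma)
    blurred = ndimage.convolve(lab[..., 0], kernel, mode="nearest")
    return np.clip(blurred, 0.0, 100.0)


def enhance_nuclei(lab: np.ndarray, settings: EnhancementSettings | None = None) -> np.ndarray:
    """Sharpen bluish (hematoxylin-stained) structures in the L* plane.

    ``detail = L* − blur(L*)``; wherever ``b* < 0`` and
    ``|detail| > threshold`` the output lightness is
    ``clip(L* + factor·detail, 0, 100)``; all other pixels, and the a*/b*
    planes everywhere, are returned unchanged.
    """
    settings = settings or EnhancementSettings()
    lab = np.asarray(lab, dtype=float)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValidationError(f"expected an (H, W, 3) LAB image, got shape {lab.shape}")
    L = lab[..., 0]
    detail = L - blur_lightness(lab, settings)
    gate = (lab[..., 2] < 0.0) & (np.abs(detail) > settings.threshold)
    out = lab.copy()
    out[..., 0] = np.where(gate, np.clip(L + settings.factor * detail, 0.0, 100.0), L)
    return out
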