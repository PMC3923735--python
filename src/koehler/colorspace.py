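"""RGB ↔ CIE XYZ ↔ CIE LAB conversions.

The conversions here use a purely linear RGB→XYZ map (the classic CIE
matrices, no gamma companding): 8-bit values are scaled by 1/255 and fed
directly through the matrix.  This deliberately differs from sRGB-aware
converters such as :func:`skimage.color.rgb2lab`; the whole correction
pipeline is self-consistent under this convention, and the reference white
is defined as the row sums of the forward matrix so that RGB white maps to
L* = 100, a* = b* = 0 exactly.

Images are plain ``float64`` arrays of shape ``(H, W, 3)``.  RGB channels
live in [0, 1]; L* in [0, 100]; a*, b* are signed.  Intermediate values are
never clamped — clamping happens only when an image is written out (see
:mod:`koehler.imgio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGB_TO_XYZ_MATRIX",
    "XYZ_TO_RGB_MATRIX",
    "WhiteReference",
    "D_WHITE",
    "f_forward",
    "f_inverse",
    "rgb_to_xyz",
    "xyz_to_rgb",
    "xyz_to_lab",
    "lab_to_xyz",
    "rgb_to_lab",
    "lab_to_rgb",
]

#: Linear RGB → XYZ tristimulus matrix (rows X, Y, Z).
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)

#: XYZ → RGB matrix (rounded inverse of the forward matrix).
XYZ_TO_RGB_MATRIX = np.array(
    [
        [3.240479, -1.537150, -0.498535],
        [-0.969256, 1.875992, 0.041556],
        [0.055648, -0.204043, 1.057311],
    ]
)


@dataclass(frozen=True)
class WhiteReference:
    """Reference white tristimulus and the constants of the LAB companding.

    ``delta = 6/29`` splits ``f(t)`` into a cube-root branch (``t > t0``,
    ``t0 = delta**3 ≈ 0.008856``) and a linear branch with slope
    ``1/(3 delta**2) ≈ 7.787037`` and intercept ``16/116``, chosen so the
    two branches match in value and slope at ``t0``.
    """

    Xn: float
    Yn: float
    Zn: float
    delta: float = field(default=6.0 / 29.0)

    def __post_init__(self) -> None:
        if min(self.Xn, self.Yn, self.Zn) <= 0:
            raise ValueError("reference white tristimulus must be positive")

    @property
    def t0(self) -> float:
        return self.delta**3

    @property
    def slope(self) -> float:
        return 1.0 / (3.0 * self.delta**2)

    @property
    def intercept(self) -> float:
        return 16.0 / 116.0

    @property
    def whitepoint(self) -> np.ndarray:
        return np.array([self.Xn, self.Yn, self.Zn])


#: Default reference white: row sums of the forward matrix, i.e. the image
#: of RGB (1, 1, 1).  Forces white → (L*, a*, b*) = (100, 0, 0) exactly.
D_WHITE = WhiteReference(*RGB_TO_XYZ_MATRIX.sum(axis=1))


def f_forward(t, ref: WhiteReference = D_WHITE):
    """Companding function ``f(t)``: cube root above ``t0``, linear below.

    Parameters
    ----------
    t : float or ndarray
        Non-negative tristimulus ratio(s), e.g. ``Y / Yn``.
    ref : WhiteReference
        Supplies ``t0``, the linear slope and the 16/116 intercept.

    Returns
    -------
    float or ndarray
        ``t**(1/3)`` where ``t > t0``, else ``slope * t + 16/116``.
        Continuous (in value and slope) at ``t0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("f_forward requires t >= 0")
    out = np.where(t > ref.t0, np.cbrt(t), ref.slope * t + ref.intercept)
    return float(out) if out.ndim == 0 else out


def f_inverse(fval, ref: WhiteReference = D_WHITE):
    """Inverse of :func:`f_forward`: cube above ``delta``, linear below.

    ``f_inverse(f) = f**3`` when ``f > delta``, else
    ``(f - 16/116) * 3 * delta**2``.  Round-trips with :func:`f_forward`
    to 1e-9 over the attainable range.
    """
    fval = np.asarray(fval, dtype=float)
    if not np.all(np.isfinite(fval)):
        raise ValueError("f_inverse requires finite input")
    out = np.where(
        fval > ref.delta,
        fval**3,
        (fval - ref.intercept) * 3.0 * ref.delta**2,
    )
    return float(out) if out.ndim == 0 else out


def _check_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"{name} must have shape (H, W, 3), got {img.shape}")
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError(f"{name} must be at least 2x2 pixels")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite values")
    return img


def rgb_to_xyz(img: np.ndarray) -> np.ndarray:
    """Linear per-pixel RGB → XYZ map (no gamma companding)."""
    img = _check_image(img, "rgb image")
    return img @ RGB_TO_XYZ_MATRIX.T


def xyz_to_rgb(img: np.ndarray) -> np.ndarray:
    """Per-pixel XYZ → RGB map by the rounded inverse matrix.

    Output is *not* clamped; values may transiently leave [0, 1] and are
    only clipped on write-out.
    """
    img = _check_image(img, "xyz image")
    return img @ XYZ_TO_RGB_MATRIX.T


def xyz_to_lab(img: np.ndarray, ref: WhiteReference = D_WHITE) -> np.ndarray:
    """XYZ → LAB: L* = 116 f(Y/Yn) − 16, a* = 500 (f(X/Xn) − f(Y/Yn)),
    b* = 200 (f(Y/Yn) − f(Z/Zn))."""
    img = _check_image(img, "xyz image")
    ratios = np.clip(img, 0.0, None) / ref.whitepoint
    fx, fy, fz = (f_forward(ratios[..., i], ref) for i in range(3))
    lab = np.empty_like(img)
    lab[..., 0] = 116.0 * fy - 16.0
    lab[..., 1] = 500.0 * (fx - fy)
    lab[..., 2] = 200.0 * (fy - fz)
    return lab


def lab_to_xyz(img: np.ndarray, ref: WhiteReference = D_WHITE) -> np.ndarray:
    """LAB → XYZ, inverting :func:`xyz_to_lab` channel-wise.

    ``fy = (L* + 16)/116`` and ``fx = fy + a*/500`` follow the standard
    reverse rules; ``fz = fy - b*/200`` is the expression that inverts the
    forward definition ``b* = 200 (fy - fz)`` (a chain through ``fx`` would
    not).
    """
    img = _check_image(img, "lab image")
    fy = (img[..., 0] + 16.0) / 116.0
    fx = fy + img[..., 1] / 500.0
    fz = fy - img[..., 2] / 200.0
    xyz = np.empty_like(img)
    xyz[..., 0] = ref.Xn * f_inverse(fx, ref)
    xyz[..., 1] = ref.Yn * f_inverse(fy, ref)
    xyz[..., 2] = ref.Zn * f_inverse(fz, ref)
    return xyz


def rgb_to_lab(img: np.ndarray, ref: WhiteReference = D_WHITE) -> np.ndarray:
    """RGB → LAB through the XYZ intermediate."""
    return xyz_to_lab(rgb_to_xyz(img), ref)


def lab_to_rgb(img: np.ndarray, ref: WhiteReference = D_WHITE) -> np.ndarray:
    """LAB → RGB through the XYZ intermediate (unclamped)."""
    return xyz_to_rgb(lab_to_xyz(img, ref))
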