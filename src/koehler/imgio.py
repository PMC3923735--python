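"""Reading and writing 8/16-bit RGB rasters (PNG, TIFF) and float masks.

All in-memory images are float64 in [0, 1]; quantization to integer counts
happens only here.  Alpha channels are dropped with a logged warning;
grayscale inputs are rejected because the method operates on color.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import GrayscaleInputError

__all__ = ["read_rgb", "write_rgb", "write_mask", "read_mask", "to_uint8", "from_uint8"]

logger = logging.getLogger(__name__)

_GRAY_MODES = {"L", "LA", "I", "I;16", "F", "1"}


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Clamp to [0, 1] and quantize to 8-bit counts."""
    return np.rint(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)


def from_uint8(img: np.ndarray) -> np.ndarray:
    """Scale 8-bit counts to floats in [0, 1]."""
    return np.asarray(img, dtype=float) / 255.0


def read_rgb(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as an (H, W, 3) float array in [0, 1].

    Raises
    ------
    GrayscaleInputError
        If the file has no color channels.
    """
    with Image.open(path) as im:
        if im.mode in _GRAY_MODES:
            raise GrayscaleInputError(
                f"{path}: grayscale input rejected; an RGB H&E image is required"
            )
        if im.mode not in ("RGB", "RGBA"):
            im = im.convert("RGBA" if "A" in im.mode or im.mode == "P" else "RGB")
        if im.mode == "RGBA":
            logger.warning("%s: dropping alpha channel", path)
            im = im.convert("RGB")
        arr = np.asarray(im)
    return from_uint8(arr)


def write_rgb(path: str | Path, img: np.ndarray, bit_depth: int = 8) -> None:
    """Write an RGB float image, clamped, as 8-bit PNG/TIFF or 16-bit TIFF."""
    path = Path(path)
    if bit_depth == 8:
        data = to_uint8(img)
    elif bit_depth == 16:
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("16-bit output is only supported for TIFF")
        data = np.rint(np.clip(img, 0.0, 1.0) * 65535.0).astype(np.uint16)
    else:
        raise ValueError(f"unsupported bit depth {bit_depth}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data, photometric="rgb")
    else:
        Image.fromarray(data, mode="RGB").save(path)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write an illumination mask as a 32-bit float single-plane TIFF."""
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=np.float32))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a float mask TIFF back as float64."""
    return tifffile.imread(Path(path)).astype(float)
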