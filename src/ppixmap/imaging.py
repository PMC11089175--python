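"""Image data model and file I/O.

Images are plain numpy arrays throughout the package:

* RGB frames (the camera's original image) are ``(H, W, 3) uint8`` arrays,
  channels ordered R, G, B, each value in [0, 255].
* Scalar planes (fluorescence intensity in arbitrary units, boolean masks,
  ground-truth labels) are 2-D arrays of the same height and width.

Pixel coordinates are 0-based, row-major, origin at the top-left corner;
every module in the package uses this convention.

PNG is the canonical (lossless) output format; TIFF is accepted on read,
with 16-bit samples rescaled to 8-bit. JPEG input is accepted with a logged
warning because its lossy compression degrades colorimetry; JPEG is never
written.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "UnsupportedImageError",
    "read_image",
    "write_image",
    "round_half_up",
    "validate_rgb",
]

log = logging.getLogger(__name__)


class UnsupportedImageError(ValueError):
    """Raised for inputs outside the supported RGB(A) 8/16-bit contract."""


def round_half_up(x: np.ndarray | float) -> np.ndarray:
    """Round to the nearest integer with ties going up (0.5 -> 1).

    numpy's ``round`` uses banker's rounding; image quantisation here must be
    deterministic and endpoint-preserving, so half-up is used everywhere.
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a valid (H, W, 3) uint8 RGB image and return it."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise UnsupportedImageError(
            f"expected an (H, W, 3) RGB array, got shape {img.shape}"
        )
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise UnsupportedImageError(f"image dimensions must be >= 1, got {img.shape[:2]}")
    if img.dtype != np.uint8:
        raise UnsupportedImageError(f"expected uint8 channels, got dtype {img.dtype}")
    return img


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF (or, with a warning, JPEG) file as an (H, W, 3) uint8 array.

    16-bit samples are rescaled to [0, 255] as ``round_half_up(v * 255 / 65535)``
    so that full scale maps to full scale. An alpha channel, if present, is
    dropped with a logged warning. Grayscale input is rejected: the colorimetry
    stage needs all three channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if path.suffix.lower() in (".jpg", ".jpeg"):
        log.warning("reading lossy JPEG %s; colorimetry on JPEG is degraded", path)
    arr = iio.imread(path)
    arr = np.asarray(arr)

    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise UnsupportedImageError(
            f"{path}: single-channel (grayscale) input is unsupported; "
            "3 (RGB) or 4 (RGBA) channels are required"
        )
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        nchan = arr.shape[2] if arr.ndim == 3 else 1
        raise UnsupportedImageError(
            f"{path}: unsupported channel count {nchan}; expected 3 or 4"
        )
    if arr.shape[2] == 4:
        log.warning("%s: dropping alpha channel", path)
        arr = arr[:, :, :3]

    if arr.dtype == np.uint8:
        out = arr
    elif arr.dtype == np.uint16:
        out = round_half_up(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    else:
        raise UnsupportedImageError(
            f"{path}: unsupported sample dtype {arr.dtype}; expected uint8 or uint16"
        )
    return validate_rgb(np.ascontiguousarray(out))


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB image as lossless PNG; ``read_image`` round-trips bit-exactly."""
    img = validate_rgb(img)
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise ValueError(f"only lossless PNG output is supported, got {path.suffix!r}")
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    iio.imwrite(path, img, extension=".png")


def write_gray(values: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 2-D uint8 plane (intensity image or 0/255 mask) as PNG."""
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {values.shape}")
    if values.dtype != np.uint8:
        raise ValueError(f"expected uint8, got {values.dtype}")
    iio.imwrite(Path(path), values, extension=".png")


def write_rgba(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an (H, W, 4) uint8 RGBA layer as PNG (transparency preserved)."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 4 or img.dtype != np.uint8:
        raise ValueError(f"expected an (H, W, 4) uint8 array, got {img.shape} {img.dtype}")
    iio.imwrite(Path(path), img, extension=".png")
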