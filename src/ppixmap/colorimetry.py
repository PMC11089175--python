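"""Extraction of the fluorescence intensity image from a blue-light RGB frame.

Under ~405 nm blue excitation, PpIX emits around 635 nm, so fluorescing
tissue appears red/pink against the reflected blue excitation light. The
extraction turns the RGB original image into a scalar fluorescence image in
arbitrary units (au) on a relative 0-255 scale. Two colorimetry backends are
provided:

``extract_fluorescence``
    Excitation-subtracted red dominance: per pixel,
    ``au = clamp(gain * max(0, R - alpha * max(G, B)), 0, 255)``.
    Subtracting the scaled larger of G and B removes reflected blue light
    and white specular highlights, leaving the red emission.

``extract_fluorescence_hsv``
    HSV hue-band gating: a pixel contributes ``255 * value`` when its hue
    falls in a (possibly wrap-around) band and its saturation and value
    exceed floors. More robust on pinkish, weakly-saturated backgrounds.

The backends are alternative operationalizations, not equivalents; both
guarantee output in [0, 255], zero response to red-free pixels, and (for the
subtraction backend) monotonicity in R at fixed G, B. The quantification is
relative: the camera and illumination are not radiometrically calibrated,
so au values compare regions within an acquisition, not across devices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .imaging import round_half_up, validate_rgb

__all__ = ["ColorimetryParams", "extract_fluorescence", "extract_fluorescence_hsv"]


@dataclass(frozen=True)
class ColorimetryParams:
    """Parameters of the subtraction backend.

    alpha : weight of the excitation-light subtraction (dimensionless, >= 0).
    gain  : multiplicative rescale applied after subtraction (>= 0).
    """

    alpha: float = 1.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.gain < 0:
            raise ValueError(f"gain must be >= 0, got {self.gain}")


def extract_fluorescence(
    oi: np.ndarray, params: ColorimetryParams | None = None
) -> np.ndarray:
    """Subtraction-backend fluorescence image of a blue-light RGB frame.

    Returns a uint8 (H, W) array in au; values are rounded half-up after
    clamping so outputs are exactly reproducible integers.
    """
    oi = validate_rgb(oi)
    if params is None:
        params = ColorimetryParams()
    r = oi[:, :, 0].astype(np.float64)
    gb = np.maximum(oi[:, :, 1], oi[:, :, 2]).astype(np.float64)
    au = params.gain * np.maximum(0.0, r - params.alpha * gb)
    return round_half_up(np.clip(au, 0.0, 255.0)).astype(np.uint8)


def extract_fluorescence_hsv(
    oi: np.ndarray,
    hue_band: tuple[float, float] = (320.0, 30.0),
    sat_min: float = 0.3,
    val_min: float = 0.1,
) -> np.ndarray:
    """HSV-backend fluorescence image.

    Parameters
    ----------
    hue_band
        ``(lo, hi)`` in degrees on [0, 360); the band may wrap through 0
        (``lo > hi``), as the default red/magenta band does. A zero-length
        band is a parameter error.
    sat_min, val_min
        Saturation and value floors in [0, 1].

    Pixels inside the band with saturation >= ``sat_min`` and value >=
    ``val_min`` get ``round(255 * value)`` au; all others get 0.
    """
    oi = validate_rgb(oi)
    lo, hi = (float(hue_band[0]) % 360.0, float(hue_band[1]) % 360.0)
    if lo == hi:
        raise ValueError(f"hue_band is empty: {hue_band}")
    for name, v in (("sat_min", sat_min), ("val_min", val_min)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")

    hsv = rgb2hsv(oi)
    hue = hsv[:, :, 0] * 360.0
    sat = hsv[:, :, 1]
    val = hsv[:, :, 2]
    if lo < hi:
        in_band = (hue >= lo) & (hue <= hi)
    else:  # band wraps through 0 degrees
        in_band = (hue >= lo) | (hue <= hi)
    keep = in_band & (sat >= sat_min) & (val >= val_min)
    au = np.where(keep, round_half_up(255.0 * val), 0.0)
    return au.astype(np.uint8)
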