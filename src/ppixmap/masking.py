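"""Threshold segmentation of the fluorescence image into a boolean mask.

The mask marks super-threshold fluorescence. Thresholding is inclusive
(``au >= threshold``) so the saturated 255 case is unambiguous. Optional
cleanup: morphological opening then closing with a disk (speckle removal
first, then pinhole sealing), followed by removal of 8-connected components
smaller than a minimum area. With ``morph_radius=0`` and ``min_area=0`` the
result is exactly the bare per-pixel comparison.

8-connectivity is used throughout the package: visually contiguous
fluorescent zones must not split on diagonal contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _sk_label
from skimage.morphology import closing, disk, opening, remove_small_objects

__all__ = ["MaskParams", "compute_mask", "label_components"]


@dataclass(frozen=True)
class MaskParams:
    """Segmentation parameters.

    threshold    : inclusive fluorescence floor in au, [0, 255]. The default
                   30 au is a low-fluorescence floor against background noise;
                   it is a tunable, not a calibrated constant.
    min_area     : components smaller than this many pixels are dropped.
    morph_radius : disk radius for opening/closing; 0 skips morphology.
    """

    threshold: int = 30
    min_area: int = 25
    morph_radius: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold must be in [0, 255], got {self.threshold}")
        if self.min_area < 0:
            raise ValueError(f"min_area must be >= 0, got {self.min_area}")
        if self.morph_radius < 0:
            raise ValueError(f"morph_radius must be >= 0, got {self.morph_radius}")


def compute_mask(afi: np.ndarray, params: MaskParams | None = None) -> np.ndarray:
    """Boolean fluorescence mask of a scalar au image."""
    afi = np.asarray(afi)
    if afi.ndim != 2:
        raise ValueError(f"expected a 2-D au image, got shape {afi.shape}")
    if params is None:
        params = MaskParams()
    mask = afi >= params.threshold
    if params.morph_radius > 0:
        selem = disk(params.morph_radius)
        mask = opening(mask, selem)
        mask = closing(mask, selem)
    if params.min_area > 0:
        # drop components with area strictly below min_area
        mask = remove_small_objects(mask, max_size=params.min_area - 1, connectivity=2)
    return mask


def label_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Label 8-connected components 1..K; background stays 0.

    Labels are assigned deterministically in raster-scan order of each
    component's first pixel, independent of the underlying labelling
    routine's internal order.
    """
    mask = np.asarray(mask).astype(bool)
    raw = _sk_label(mask, connectivity=2)
    n = int(raw.max())
    if n == 0:
        return np.zeros_like(raw, dtype=np.int32), 0
    flat = raw.ravel()
    # first raster index of each label 1..n
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first[flat[idx[::-1]]] = idx[::-1]
    order = np.argsort(first[1:], kind="stable")  # old labels sorted by first pixel
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1, dtype=np.int32)
    return remap[raw], n
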