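"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: component
counting is a hand-written BFS flood fill, mask filling goes through
matplotlib's point-in-polygon test, and expected au values come from the
closed-form arithmetic stated in the module contracts.
"""

from collections import deque

import numpy as np
import pytest
from skimage.filters import gaussian


def flood_fill_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """BFS 8-connected labelling, raster-scan seeded. Independent oracle."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)
    k = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                k += 1
                q = deque([(r0, c0)])
                labels[r0, c0] = k
                while q:
                    r, c = q.popleft()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                                labels[rr, cc] = k
                                q.append((rr, cc))
    return labels, k


def random_blob_mask(rng: np.random.Generator, shape=(64, 64), sigma=3.0, frac=0.35) -> np.ndarray:
    """Random smooth blob mask: smoothed noise thresholded at a quantile."""
    noise = gaussian(rng.normal(size=shape), sigma=sigma)
    return noise > np.quantile(noise, 1.0 - frac)


@pytest.fixture
def rng():
    return np.random.default_rng(20240429)
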