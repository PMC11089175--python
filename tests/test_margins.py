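"""Safety-margin contours and overlay compositing."""

import numpy as np
import pytest

from ppixmap.mapping import build_intensity_map
from ppixmap.margins import extract_safety_margin, overlay, rasterize_margin

from conftest import random_blob_mask


def shoelace_area(vertices):
    x, y = vertices[:, 1], vertices[:, 0]
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def test_empty_mask_gives_no_contours():
    sm = extract_safety_margin(np.zeros((8, 8), dtype=bool))
    assert sm.contours == []


def test_rectangle_contour_area_matches_pixel_count():
    mask = np.zeros((20, 30), dtype=bool)
    mask[5:15, 8:24] = True  # 10 x 16 = 160 px
    sm = extract_safety_margin(mask)
    assert len(sm.contours) == 1
    c = sm.contours[0]
    assert not c.is_hole
    assert np.array_equal(c.vertices[0], c.vertices[-1]) and len(c.vertices) >= 4
    area = shoelace_area(c.vertices)
    perimeter = 2 * (10 + 16)
    assert abs(area - 160) <= perimeter / 2  # half-pixel boundary placement
    assert area > 0  # outer-ring orientation convention


def test_ring_mask_yields_outer_plus_hole():
    mask = np.zeros((20, 20), dtype=bool)
    mask[4:16, 4:16] = True
    mask[8:12, 8:12] = False
    sm = extract_safety_margin(mask)
    assert len(sm.contours) == 2
    holes = [c for c in sm.contours if c.is_hole]
    outers = [c for c in sm.contours if not c.is_hole]
    assert len(holes) == 1 and len(outers) == 1
    assert holes[0].parent == sm.contours.index(outers[0])
    assert shoelace_area(holes[0].vertices) < 0


def test_contour_fill_reproduces_mask_on_random_blobs(rng):
    """Even-odd filling of the rings inverts contour extraction exactly."""
    for _ in range(25):
        mask = random_blob_mask(rng, (64, 64), sigma=float(rng.uniform(1.0, 4.0)))
        sm = extract_safety_margin(mask)
        assert np.array_equal(rasterize_margin(sm, mask.shape), mask)


def test_outward_dilation_strictly_grows_margin():
    mask = np.zeros((30, 30), dtype=bool)
    mask[10:20, 10:20] = True
    base = extract_safety_margin(mask)
    grown = extract_safety_margin(mask, dilation_radius=2)
    assert shoelace_area(grown.contours[0].vertices) > shoelace_area(base.contours[0].vertices)


def test_extraction_is_deterministic(rng):
    mask = random_blob_mask(rng, (48, 48))
    a = extract_safety_margin(mask)
    b = extract_safety_margin(mask)
    assert len(a.contours) == len(b.contours)
    for ca, cb in zip(a.contours, b.contours):
        assert np.array_equal(ca.vertices, cb.vertices)
        assert (ca.is_hole, ca.parent) == (cb.is_hole, cb.parent)


def test_geojson_rings_nest_holes_under_outers():
    mask = np.zeros((20, 20), dtype=bool)
    mask[4:16, 4:16] = True
    mask[8:12, 8:12] = False
    gj = extract_safety_margin(mask).to_geojson_dict()
    assert len(gj["geometries"]) == 1
    assert len(gj["geometries"][0]["coordinates"]) == 2  # outer + hole ring


def _phantom_layers(rng, shape=(32, 32)):
    oi = rng.integers(0, 256, size=shape + (3,), dtype=np.uint8)
    afi = rng.integers(0, 256, size=shape, dtype=np.uint8)
    mask = np.zeros(shape, dtype=bool)
    mask[8:20, 10:22] = True
    im = build_intensity_map(afi, mask)
    sm = extract_safety_margin(mask)
    return oi, im, sm, mask


def test_empty_layers_return_input_bit_exactly(rng):
    oi = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
    empty_mask = np.zeros((16, 16), dtype=bool)
    im = build_intensity_map(np.zeros((16, 16), np.uint8), empty_mask)
    sm = extract_safety_margin(empty_mask)
    assert np.array_equal(overlay(oi, im, sm), oi)


def test_alpha_zero_touches_only_contour_pixels(rng):
    oi, im, sm, mask = _phantom_layers(rng)
    out = overlay(oi, im, sm, im_alpha=0.0)
    diff = (out != oi).any(axis=2)
    assert diff.any()
    # differences confined to a band around the margin contour
    from skimage.morphology import dilation, disk

    band = dilation(mask, disk(2)) & ~_erode(mask)
    assert not (diff & ~band).any()


def _erode(mask):
    from skimage.morphology import disk, erosion

    return erosion(mask, disk(3))


def test_alpha_one_paints_exact_colormap_colors(rng):
    oi, im, sm, mask = _phantom_layers(rng)
    out = overlay(oi, im, None, im_alpha=1.0)
    assert np.array_equal(out[mask], im.rgba[mask][:, :3])


def test_untouched_pixels_are_bit_identical(rng):
    oi, im, sm, mask = _phantom_layers(rng)
    out = overlay(oi, im, sm)
    from skimage.morphology import dilation, disk

    touched = dilation(mask, disk(2))
    assert np.array_equal(out[~touched], oi[~touched])


def test_dimension_mismatch_names_both_shapes(rng):
    oi = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
    im = build_intensity_map(np.zeros((4, 4), np.uint8), np.ones((4, 4), bool))
    with pytest.raises(ValueError, match=r"\(8, 8\).*\(4, 4\)"):
        overlay(oi, im, None)
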