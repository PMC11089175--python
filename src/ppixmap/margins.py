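"""Safety-margin contours and overlay rendering.

The safety margin outlines the fluorescent zone of the boolean mask with
sub-pixel iso-contours, one closed outer ring per 8-connected component plus
rings for any holes. Contours are traced at iso-level 0.5 on the 0/1 mask
field (marching squares, saddle cells resolved toward 8-connected
foreground), so they run halfway between foreground and background pixel
centers — the documented half-pixel boundary convention.

Coordinate and orientation conventions (fixed for serialization):

* vertices are (row, col) floats, 0-based, pixel centers at integers;
* rings are closed (first vertex equals last) with >= 4 vertices;
* outer rings have positive shoelace area computed over (col, row) taken as
  (x, y); hole rings have negative area. With the image row axis pointing
  down this makes outer rings counter-clockwise in the mathematical (y-up)
  sense.

``overlay`` composites the intensity map and the margin polylines onto the
original image; pixels outside the mask and away from the drawn contour
lines are returned bit-identical to the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import Point, Polygon
from skimage.draw import line as draw_line
from skimage.measure import find_contours
from skimage.morphology import dilation, disk

from .imaging import round_half_up, validate_rgb
from .mapping import IntensityMap

__all__ = ["Contour", "SafetyMargin", "extract_safety_margin", "rasterize_margin", "overlay"]


@dataclass(frozen=True)
class Contour:
    """One closed ring of the safety margin."""

    vertices: np.ndarray  # (N, 2) float64 (row, col); vertices[0] == vertices[-1]
    is_hole: bool
    parent: int | None  # index into SafetyMargin.contours of the enclosing outer ring


@dataclass
class SafetyMargin:
    """Set of closed margin rings extracted from a fluorescence mask."""

    contours: list[Contour] = field(default_factory=list)

    def to_geojson_dict(self) -> dict:
        """GeoJSON-style polygons: outer rings with their holes as inner rings.

        Coordinates are [row, col] floats in pixel space.
        """
        polys = []
        for i, c in enumerate(self.contours):
            if c.is_hole:
                continue
            rings = [c.vertices.tolist()]
            rings += [
                h.vertices.tolist()
                for h in self.contours
                if h.is_hole and h.parent == i
            ]
            polys.append({"type": "Polygon", "coordinates": rings})
        return {"type": "GeometryCollection", "geometries": polys}


def _signed_area(vertices: np.ndarray) -> float:
    """Shoelace area over (col, row) as (x, y); positive = outer-ring orientation."""
    x = vertices[:, 1]
    y = vertices[:, 0]
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def extract_safety_margin(mask: np.ndarray, dilation_radius: int = 0) -> SafetyMargin:
    """Trace sub-pixel margin contours of a boolean mask.

    ``dilation_radius`` > 0 pushes the margin outward by that many pixels
    before tracing (a conservative resection margin); the default 0 places
    the contour at the mask boundary.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {mask.shape}")
    if dilation_radius > 0:
        mask = dilation(mask, disk(dilation_radius))
    if not mask.any():
        return SafetyMargin(contours=[])

    # Pad with background so components touching the border close properly.
    padded = np.pad(mask.astype(np.float64), 1)
    raw = find_contours(padded, level=0.5, fully_connected="high")

    loops = []
    for verts in raw:
        verts = np.asarray(verts, dtype=np.float64) - 1.0  # undo padding offset
        if not np.array_equal(verts[0], verts[-1]):
            verts = np.vstack([verts, verts[:1]])
        if len(verts) < 4:
            continue
        loops.append(verts)
    # deterministic ordering: raster order of each ring's topmost-leftmost vertex
    loops.sort(key=lambda v: (float(v[:, 0].min()), float(v[v[:, 0].argmin(), 1])))

    polys = [Polygon(v[:, ::-1]) for v in loops]  # shapely wants (x, y) = (col, row)
    depth = []
    for i, v in enumerate(loops):
        d = sum(1 for j, p in enumerate(polys) if j != i and p.contains(Point(v[0, 1], v[0, 0])))
        depth.append(d)

    contours: list[Contour] = []
    for i, v in enumerate(loops):
        is_hole = depth[i] % 2 == 1
        want_positive = not is_hole
        if (_signed_area(v) > 0) != want_positive:
            v = v[::-1].copy()
        parent = None
        if is_hole:
            # innermost enclosing ring of even depth
            best = -1
            for j, p in enumerate(polys):
                if j != i and depth[j] == depth[i] - 1 and p.contains(Point(loops[i][0, 1], loops[i][0, 0])):
                    if depth[j] > best:
                        best = depth[j]
                        parent = j
        contours.append(Contour(vertices=v, is_hole=is_hole, parent=parent))
    return SafetyMargin(contours=contours)


def rasterize_margin(sm: SafetyMargin, shape: tuple[int, int]) -> np.ndarray:
    """Fill the margin rings back into a boolean mask (even-odd rule).

    Pixel centers inside an odd number of rings are foreground. Because the
    rings sit half a pixel away from every center, this inverts
    ``extract_safety_margin`` exactly on the original mask.
    """
    rows, cols = np.indices(shape)
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(np.float64)
    count = np.zeros(shape[0] * shape[1], dtype=np.int64)
    for c in sm.contours:
        path = MplPath(c.vertices[:, ::-1])  # (x, y) = (col, row)
        count += path.contains_points(pts)
    return (count % 2 == 1).reshape(shape)


def overlay(
    oi: np.ndarray,
    im: IntensityMap | None,
    sm: SafetyMargin | None,
    im_alpha: float = 0.5,
    sm_color: tuple[int, int, int] = (0, 255, 0),
    sm_width: int = 2,
) -> np.ndarray:
    """Composite intensity map and safety margin onto the original image.

    The intensity map is alpha-blended at ``im_alpha`` where its own alpha
    channel is set (``out = im_alpha * layer + (1 - im_alpha) * oi``, rounded
    half-up); margin rings are then rasterized on top as ``sm_color``
    polylines of approximate width ``sm_width`` pixels. Either layer may be
    None to skip it.
    """
    oi = validate_rgb(oi)
    if not 0.0 <= im_alpha <= 1.0:
        raise ValueError(f"im_alpha must be in [0, 1], got {im_alpha}")
    out = oi.astype(np.float64)

    if im is not None:
        if im.rgba.shape[:2] != oi.shape[:2]:
            raise ValueError(
                f"dimension mismatch: original {oi.shape[:2]} vs intensity map {im.rgba.shape[:2]}"
            )
        sel = im.rgba[:, :, 3] > 0
        layer = im.rgba[:, :, :3].astype(np.float64)
        out[sel] = im_alpha * layer[sel] + (1.0 - im_alpha) * out[sel]

    out = round_half_up(out).astype(np.uint8)

    if sm is not None and sm.contours:
        h, w = oi.shape[:2]
        stroke = np.zeros((h, w), dtype=bool)
        for c in sm.contours:
            v = round_half_up(c.vertices).astype(np.int64)
            v[:, 0] = np.clip(v[:, 0], 0, h - 1)
            v[:, 1] = np.clip(v[:, 1], 0, w - 1)
            for (r0, c0), (r1, c1) in zip(v[:-1], v[1:]):
                rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
                stroke[rr, cc] = True
        if sm_width > 1:
            stroke = dilation(stroke, disk(sm_width // 2))
        out[stroke] = np.asarray(sm_color, dtype=np.uint8)
    return out
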