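"""Rotated-rectangle morphometry of binary silhouettes.

Particle size is defined by the minimum-area rectangle circumscribed
around the silhouette: ``H`` is the long side, and the morphological
parameter ``M`` is the short/long side ratio (0 for a line, 1 for a
circle or square).  The rectangle is computed from the *corners* of the
boundary pixels so that an axis-aligned ``r x c`` pixel block measures
exactly ``r x c`` pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint


@dataclass(frozen=True)
class RotatedRect:
    """Minimum-area circumscribed rectangle, lengths in pixels."""

    length: float          # long side
    width: float           # short side
    angle_deg: float       # orientation of the long side w.r.t. the column axis
    center: tuple[float, float]  # (row, col)

    @property
    def aspect(self) -> float:
        """Width/length ratio M in [0, 1]."""
        if self.length == 0:
            return 1.0
        return self.width / self.length


def _boundary_corner_points(mask: np.ndarray) -> np.ndarray:
    """Corner coordinates (row, col) of the boundary pixels of a mask."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, border_value=0)
    boundary = mask & ~eroded
    rc = np.argwhere(boundary).astype(float)
    if rc.size == 0:
        raise ValueError("empty mask")
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    return (rc[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


def min_area_rect(mask: np.ndarray) -> RotatedRect:
    """Minimum-area rotated rectangle circumscribing a binary mask.

    Works on boundary-pixel corners, so a solid axis-aligned block of
    ``a x b`` pixels yields ``length = max(a, b)`` exactly.
    """
    pts = _boundary_corner_points(mask)
    # shapely expects (x, y); feed (col, row)
    hull = MultiPoint(np.c_[pts[:, 1], pts[:, 0]]).convex_hull
    rect = shapely.oriented_envelope(hull)
    if rect.geom_type == "Point":  # single pixel
        r, c = pts.mean(axis=0)
        return RotatedRect(1.0, 1.0, 0.0, (r, c))
    if rect.geom_type == "LineString":
        (x0, y0), (x1, y1) = rect.coords[0], rect.coords[-1]
        length = float(np.hypot(x1 - x0, y1 - y0))
        ang = float(np.degrees(np.arctan2(y1 - y0, x1 - x0)))
        return RotatedRect(length, 0.0, ang, ((y0 + y1) / 2, (x0 + x1) / 2))
    xy = np.asarray(rect.exterior.coords)[:4]
    e1 = xy[1] - xy[0]
    e2 = xy[2] - xy[1]
    l1, l2 = np.hypot(*e1), np.hypot(*e2)
    if l1 >= l2:
        length, width, vec = l1, l2, e1
    else:
        length, width, vec = l2, l1, e2
    angle = float(np.degrees(np.arctan2(vec[1], vec[0]))) % 180.0
    cx, cy = xy[:4].mean(axis=0)
    return RotatedRect(float(length), float(width), angle, (float(cy), float(cx)))


def max_inscribed_radius(mask: np.ndarray) -> float:
    """Radius (px) of the largest disc that fits inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    return float(ndimage.distance_transform_edt(mask).max())
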