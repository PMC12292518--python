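"""Shared geometric primitives: the angle convention and rasterization.

Convention used throughout the package: image coordinates have the origin at
the top-left pixel, x pointing right, y pointing down, 0-based indices.
Angles are in degrees and positive angles are counter-clockwise in the
(x, -y) frame, i.e. the direction of cervical extension when the subject
faces right.  A pixel belongs to a polygon when its *center* lies inside.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy import ndimage


def rotation_matrix_deg(theta_deg: float) -> np.ndarray:
    """2x2 matrix rotating image-coordinate points (x, y) by ``theta_deg``.

    Positive angles rotate counter-clockwise in the (x, -y) frame, which is
    clockwise when drawn with y pointing down.
    """
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, s], [-s, c]])


def polygon_area(vertices: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon given as (N, 2) vertices."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon into a binary (H, W) mask.

    A pixel (row r, column c) is foreground exactly when its center (c, r)
    lies strictly inside the polygon.
    """
    h, w = shape
    poly = shapely.Polygon(vertices)
    xmin, ymin, xmax, ymax = poly.bounds
    c0 = max(0, int(np.floor(xmin)))
    c1 = min(w - 1, int(np.ceil(xmax)))
    r0 = max(0, int(np.floor(ymin)))
    r1 = min(h - 1, int(np.ceil(ymax)))
    mask = np.zeros(shape, dtype=np.uint8)
    if c1 < c0 or r1 < r0:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.contains_xy(poly, cols.ravel().astype(float), rows.ravel().astype(float))
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(rows.shape)
    return mask


def mask_centroid(mask: np.ndarray) -> np.ndarray:
    """Centroid of foreground pixels as (x, y); requires a nonempty mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("centroid of an empty mask is undefined")
    return np.array([cols.mean(), rows.mean()])


def rotate_mask(mask: np.ndarray, theta_deg: float, center: np.ndarray | None = None) -> np.ndarray:
    """Rotate a binary mask by ``theta_deg`` about ``center`` (default: its centroid).

    Bilinear resampling followed by re-binarization at 0.5, matching the
    package-wide pixel-center convention as closely as a resampled grid can.
    """
    if center is None:
        center = mask_centroid(mask)
    rot = rotation_matrix_deg(-theta_deg)  # inverse map: output -> input
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - center[0], yy - center[1]
    xs = rot[0, 0] * dx + rot[0, 1] * dy + center[0]
    ys = rot[1, 0] * dx + rot[1, 1] * dy + center[1]
    vals = ndimage.map_coordinates(mask.astype(np.float32), [ys, xs], order=1, cval=0.0)
    return (vals >= 0.5).astype(np.uint8)
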