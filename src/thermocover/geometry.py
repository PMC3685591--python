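"""Shared raster geometry for rotated square pulse footprints.

All coordinates are (row, col) with 0-based indexing; angles are degrees.
The rotation convention used throughout the package maps a point (u, v) in
the square's own frame (u along the first edge, v along the second) to a
world offset

    d_col = u * cos(a) - v * sin(a)
    d_row = u * sin(a) + v * cos(a)

so that angle 0 gives an axis-aligned square and the angle is shared by
every footprint in a scene.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["rotated_square_mask", "square_corners", "frame_coords"]


def frame_coords(
    shape: tuple[int, int],
    center: tuple[float, float],
    angle_deg: float,
    margin: float,
) -> tuple[slice, slice, np.ndarray, np.ndarray]:
    """Local (u, v) coordinates of pixel centers inside a bounding window.

    Returns (row_slice, col_slice, u, v) where ``u``/``v`` are arrays for the
    window ``[row_slice, col_slice]`` expressed in the rotated frame centred
    on ``center``.  ``margin`` is the half-extent (in pixels) of the window
    around the centre.
    """
    r0, c0 = center
    rlo = max(int(math.floor(r0 - margin)), 0)
    rhi = min(int(math.ceil(r0 + margin)) + 1, shape[0])
    clo = max(int(math.floor(c0 - margin)), 0)
    chi = min(int(math.ceil(c0 + margin)) + 1, shape[1])
    rlo, clo = min(rlo, shape[0]), min(clo, shape[1])
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr = rr - r0
    dc = cc - c0
    a = math.radians(angle_deg)
    cos_a, sin_a = math.cos(a), math.sin(a)
    u = dc * cos_a + dr * sin_a
    v = -dc * sin_a + dr * cos_a
    return slice(rlo, rhi), slice(clo, chi), u, v


def rotated_square_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    side: float,
    angle_deg: float,
) -> np.ndarray:
    """Rasterize a filled rotated square.

    A pixel belongs to the square iff its centre satisfies
    ``-side/2 <= u < side/2`` and ``-side/2 <= v < side/2`` in the square's
    frame (half-open on the max edges, which keeps abutting squares
    non-overlapping when tiled edge to edge).
    """
    if side <= 0:
        raise ValueError(f"square side must be positive, got {side}")
    half = side / 2.0
    margin = side * math.sqrt(2) / 2.0 + 1.0
    rs, cs, u, v = frame_coords(shape, center, angle_deg, margin)
    inside = (u >= -half) & (u < half) & (v >= -half) & (v < half)
    mask = np.zeros(shape, dtype=bool)
    mask[rs, cs] = inside
    return mask


def square_corners(
    center: tuple[float, float], side: float, angle_deg: float
) -> np.ndarray:
    """Corner coordinates (4, 2) of a rotated square, as (row, col)."""
    half = side / 2.0
    a = math.radians(angle_deg)
    cos_a, sin_a = math.cos(a), math.sin(a)
    corners = []
    for u, v in ((-half, -half), (half, -half), (half, half), (-half, half)):
        dc = u * cos_a - v * sin_a
        dr = u * sin_a + v * cos_a
        corners.append((center[0] + dr, center[1] + dc))
    return np.asarray(corners)
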