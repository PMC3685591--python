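"""Pulse-footprint geometry: grid angle, watershed segmentation, square fits.

Within the treated region the individual laser pulse footprints form an
approximately regular square grid whose only unknown geometric parameter
is the common rotation angle alpha*.  The angle is recovered from the
Radon transform of the Canny edge image: edge segments of the grid line up
along two orthogonal directions, so the projection taken along a grid
direction concentrates many edge pixels into single bins and the sharpest
projection peak identifies alpha* (modulo 90 degrees, since a square grid
is 90-degree symmetric).  Footprints are then separated by
marker-controlled watershed on the detrended temperature topography and
each is approximated by a rotated square of a shared, robustly estimated
side length.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.ndimage as ndi
from skimage import feature, measure, morphology, segmentation

from .geometry import rotated_square_mask
from .preprocessing import RoiMask

__all__ = [
    "EdgeImage",
    "RadonSinogram",
    "PulseArea",
    "canny_edges",
    "radon_transform",
    "estimate_grid_angle",
    "derotate",
    "rotate_points",
    "remove_constant_component",
    "watershed_pulses",
    "fit_squares",
]


class AngleEstimationError(ValueError):
    """Raised when no dominant grid direction can be identified."""


class NoPulsesError(ValueError):
    """Raised when pulse segmentation finds nothing usable."""


@dataclasses.dataclass
class EdgeImage:
    """Binary edge mask restricted to the treated region."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_edge_pixels(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class RadonSinogram:
    """Line-integral projections of an edge image over sampled angles.

    ``values[offset, angle]`` with ``angles_deg`` covering [0, 90) and
    ``offsets`` the projection offsets in pixels about the edge centroid.
    For a binary input the per-angle total mass equals the number of edge
    pixels exactly.
    """

    values: np.ndarray
    angles_deg: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("sinogram of a binary edge image must be nonnegative")


@dataclasses.dataclass
class PulseArea:
    """One detected pulse footprint as a filled rotated square."""

    center: tuple[float, float]
    side_px: float
    angle_deg: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.side_px <= 0:
            raise ValueError("pulse side must be positive")


def canny_edges(
    values: np.ndarray,
    roi: RoiMask,
    low: float = 0.1,
    high: float = 0.3,
    sigma: float = 2.0,
    dilate_px: int = 3,
) -> EdgeImage:
    """Canny edge detection restricted to the dilated treated region.

    ``low``/``high`` are hysteresis thresholds on the Gaussian gradient
    magnitude in degC per pixel; with a pulse elevation near 2.5 degC the
    footprint edges sit far above the noise floor, so the defaults are not
    critical.
    """
    if not high > low >= 0:
        raise ValueError(f"need high > low >= 0, got low={low}, high={high}")
    region = ndi.binary_dilation(roi.mask, iterations=dilate_px)
    if np.ptp(values[region]) == 0:
        warnings.warn("ROI content is constant; no edges detected", stacklevel=2)
        return EdgeImage(mask=np.zeros_like(roi.mask))
    edges = feature.canny(
        np.asarray(values, dtype=float),
        sigma=sigma,
        low_threshold=low,
        high_threshold=high,
        mask=region,
    )
    return EdgeImage(mask=edges)


def radon_transform(
    edges: EdgeImage, angle_step_deg: float = 1.0
) -> RadonSinogram:
    """Radon transform of a binary edge image over angles [0, 90).

    Computed by direct summation: every edge pixel contributes exactly one
    count to the projection bin at its rounded rotated offset
    ``n' = round(x cos(a) + y sin(a))`` (coordinates about the edge
    centroid).  Mass is therefore conserved exactly per angle - the
    per-angle total equals the number of edge pixels - unlike
    interpolation-based transforms, whose per-angle totals fluctuate on
    sparse binary inputs.
    """
    if edges.n_edge_pixels == 0:
        raise AngleEstimationError("no edges for angle estimation")
    rr, cc = np.nonzero(edges.mask)
    y = rr - rr.mean()
    x = cc - cc.mean()
    angles = np.arange(0.0, 90.0, angle_step_deg)
    rad = np.deg2rad(angles)
    t = x[:, None] * np.cos(rad)[None, :] + y[:, None] * np.sin(rad)[None, :]
    t_max = int(np.ceil(np.abs(t).max())) + 1 if t.size else 1
    offsets = np.arange(-t_max, t_max + 1)
    bins = np.rint(t).astype(np.intp) + t_max
    values = np.zeros((offsets.size, angles.size))
    for j in range(angles.size):
        values[:, j] = np.bincount(bins[:, j], minlength=offsets.size)
    return RadonSinogram(values=values, angles_deg=angles, offsets=offsets)


def estimate_grid_angle(
    sinogram: RadonSinogram, flatness_factor: float = 1.5
) -> float:
    """Grid rotation angle alpha* in [0, 90) from the sharpest projection peak.

    The score per angle is the maximum single projection bin (the
    maximum-of-sums criterion: when the projection direction lines up with
    a grid line, all its edge pixels fall into one bin).  A sinogram whose
    best peak is not clearly above the typical per-angle peak carries no
    dominant direction and is rejected.  Ties break toward the smallest
    angle; the result is only defined modulo 90 degrees because the square
    grid is 90-degree symmetric.
    """
    scores = sinogram.values.max(axis=0)
    best = float(scores.max())
    typical = float(np.median(scores))
    if typical <= 0 or best < flatness_factor * typical:
        raise AngleEstimationError(
            "angle not identifiable: projection peaks carry no dominant direction"
        )
    theta = float(sinogram.angles_deg[int(np.argmax(scores))])
    # the offset coordinate n' = x cos(theta) + y sin(theta) is constant
    # along lines perpendicular to (cos theta, sin theta); for the package's
    # square-frame convention the peak angle coincides with the grid angle.
    return theta % 90.0


def rotate_points(
    points_rc: np.ndarray,
    angle_deg: float,
    center_rc: tuple[float, float],
) -> np.ndarray:
    """Rotate (row, col) points about a centre by the package convention.

    This is the coordinate map that ``derotate(..., angle)`` applies to the
    pixel grid, so applying it with ``-angle`` maps derotated coordinates
    back to the original frame.
    """
    pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
    a = np.radians(angle_deg)
    dr = pts[:, 0] - center_rc[0]
    dc = pts[:, 1] - center_rc[1]
    out = np.empty_like(pts)
    out[:, 1] = center_rc[1] + dc * np.cos(a) - dr * np.sin(a)
    out[:, 0] = center_rc[0] + dc * np.sin(a) + dr * np.cos(a)
    return out


def derotate(
    arr: np.ndarray,
    angle_deg: float,
    center_rc: tuple[float, float] | None = None,
) -> np.ndarray:
    """Rotate an image or mask by ``-angle_deg`` about a centre.

    Masks (boolean arrays) are resampled nearest-neighbour so binarity is
    preserved; float images use bilinear resampling.  Together with
    :func:`rotate_points` this equalizes the position of footprints laid
    down at the estimated grid angle.
    """
    arr = np.asarray(arr)
    if center_rc is None:
        center_rc = ((arr.shape[0] - 1) / 2.0, (arr.shape[1] - 1) / 2.0)
    is_mask = arr.dtype == bool
    order = 0 if is_mask else 1
    a = np.radians(angle_deg)
    cos_a, sin_a = np.cos(a), np.sin(a)
    # inverse map: output pixel -> input pixel rotated by +angle about centre
    matrix = np.array(
        [
            [cos_a, sin_a, 0.0],
            [-sin_a, cos_a, 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    offset = np.array(center_rc) - matrix[:2, :2] @ np.array(center_rc)
    matrix[:2, 2] = offset
    out = ndi.affine_transform(
        arr.astype(float),
        matrix[:2, :2],
        offset=matrix[:2, 2],
        order=order,
        mode="constant",
        cval=0.0,
    )
    return out > 0.5 if is_mask else out


def remove_constant_component(
    values: np.ndarray,
    roi: RoiMask,
    window_px: int | None = None,
    downsample: int = 4,
) -> np.ndarray:
    """Remove the constant/slowly-varying temperature component over the ROI.

    A large-window median (computed on a decimated copy for speed, then
    resampled back) estimates the smooth background; subtracting it and
    re-centring leaves the pulse-relative topography with zero mean over
    the ROI.  The window must be wider than the treated field itself, or
    the background would track the pulse grid and flatten it; the default
    is twice the larger ROI bounding-box extent.
    """
    values = np.asarray(values, dtype=float)
    if window_px is None:
        r0, c0, r1, c1 = roi.bounding_box
        window_px = 2 * max(r1 - r0, c1 - c0) + 1
    small = values[::downsample, ::downsample]
    size = max(int(window_px) // downsample, 3)
    bg_small = ndi.median_filter(small, size=size, mode="nearest")
    zoom = (values.shape[0] / small.shape[0], values.shape[1] / small.shape[1])
    bg = ndi.zoom(bg_small, zoom, order=1, grid_mode=True, mode="nearest")
    bg = bg[: values.shape[0], : values.shape[1]]
    out = values - bg
    out -= out[roi.mask].mean()
    return out


def watershed_pulses(
    detrended: np.ndarray,
    roi: RoiMask,
    h_maxima_c: float = 0.3,
) -> np.ndarray:
    """Marker-controlled watershed separating individual pulse footprints.

    Markers are the regional maxima of the detrended topography after
    h-maxima suppression (peaks less than ``h_maxima_c`` degC above their
    surroundings are merged, which keeps sensor noise from splitting one
    footprint).  Flooding the inverted topography from those markers,
    restricted to the ROI, partitions the treated region exactly: every
    ROI pixel - including undertreated holes - is assigned to the nearest
    footprint basin.
    """
    detrended = np.asarray(detrended, dtype=float)
    if np.ptp(detrended[roi.mask]) < h_maxima_c:
        raise NoPulsesError(
            "no pulses detected (ROI topography is flat at the marker scale)"
        )
    inner = detrended.copy()
    floor = detrended.min() - 10.0 * max(h_maxima_c, 1.0)
    inner[~roi.mask] = floor
    peaks = morphology.h_maxima(inner, h_maxima_c)
    peaks &= roi.mask
    markers = measure.label(peaks, connectivity=2)
    if markers.max() == 0:
        raise NoPulsesError("no pulses detected (no regional maxima in ROI)")
    labels = segmentation.watershed(-detrended, markers=markers, mask=roi.mask)
    return labels


def fit_squares(
    labels: np.ndarray,
    angle_deg: float,
    intensity: np.ndarray | None = None,
    support: np.ndarray | None = None,
    area_bounds: tuple[float, float] = (0.25, 4.0),
) -> list[PulseArea]:
    """Approximate each labeled region by a rotated square footprint.

    All footprints come from one laser head, so a single physical side
    length exists: it is estimated as the median over regions of
    sqrt(area), where the area of a region is its treated support (the
    pixels actually above the binarization threshold) when ``support`` is
    given, and the full watershed cell otherwise.  Regions with area
    outside ``area_bounds`` times the median are discarded as spurious.
    Centres are intensity-weighted centroids when ``intensity`` (the
    detrended topography) is provided.
    """
    labels = np.asarray(labels)
    n_labels = int(labels.max())
    if n_labels == 0:
        raise NoPulsesError("no labeled regions to fit")
    counted = labels.copy()
    if support is not None:
        counted = np.where(np.asarray(support, dtype=bool), labels, 0)
    areas = np.bincount(counted.ravel(), minlength=n_labels + 1).astype(float)
    areas = areas[1:]
    positive = areas[areas > 0]
    if positive.size == 0:
        raise NoPulsesError("no valid pulse areas (all regions empty)")
    med_area = float(np.median(positive))
    lo, hi = area_bounds
    kept = [
        i + 1
        for i in range(n_labels)
        if lo * med_area <= areas[i] <= hi * med_area
    ]
    discarded = n_labels - len(kept)
    if discarded:
        warnings.warn(
            f"discarded {discarded} spurious region(s) with area outside "
            f"[{lo}, {hi}] x median",
            stacklevel=2,
        )
    if not kept:
        raise NoPulsesError("no valid pulse areas after area filtering")
    side = float(np.median(np.sqrt(areas[np.asarray(kept) - 1])))

    if intensity is not None:
        weights = np.clip(np.asarray(intensity, dtype=float), 0.0, None) + 1e-9
    else:
        weights = np.ones_like(labels, dtype=float)
    pulses = []
    for lab in kept:
        sel = labels == lab
        w = weights[sel]
        rr, cc = np.nonzero(sel)
        r0 = float(np.average(rr, weights=w))
        c0 = float(np.average(cc, weights=w))
        mask = rotated_square_mask(labels.shape, (r0, c0), side, angle_deg)
        pulses.append(
            PulseArea(center=(r0, c0), side_px=side, angle_deg=angle_deg, mask=mask)
        )
    return pulses
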