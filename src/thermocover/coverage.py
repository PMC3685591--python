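"""Coverage errors of a fractional-laser treatment.

Two percentages summarize how evenly the operator covered the treated
region L_R with pulse footprints L_i:

* ``delta_o`` - undertreatment: the percentage of L_R pixels covered by no
  footprint at all.  Untreated gaps are harmless but require a corrective
  session.
* ``delta_z`` - double dose: the percentage of L_R pixels lying in the
  overlap mask L_Z (covered by two or more footprints).  Overlap delivers
  a double irradiation dose and risks tissue damage, so it is the harmful
  error of the two.

Both are computed from per-pixel coverage counts (uncovered = count 0,
overlap = count >= 2), which reduces to the pairwise inclusion-exclusion
form when no pixel is covered more than twice and stays correct for
triple-plus overlaps.  Footprints are clipped to L_R before counting,
since both errors are defined with respect to the treated region.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import RunConfig, ThermalImage
from .preprocessing import RoiMask, binarize, extract_roi
from .pulse_geometry import (
    PulseArea,
    canny_edges,
    estimate_grid_angle,
    fit_squares,
    radon_transform,
    remove_constant_component,
    watershed_pulses,
)

__all__ = [
    "OverlapMask",
    "CoverageReport",
    "StageError",
    "coverage_count",
    "build_overlap_mask",
    "delta_o",
    "delta_z",
    "detect_pulses",
    "analyze_image",
    "threshold_sweep",
]


class StageError(RuntimeError):
    """An analysis failure tagged with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class OverlapMask:
    """Pixels covered by two or more pulse footprints (the L_Z mask)."""

    mask: np.ndarray
    n_pixels: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.n_pixels = int(self.mask.sum())


@dataclasses.dataclass
class CoverageReport:
    """Result of one image analysis.

    Percentages are stored at full precision here and rounded to two
    decimals in the JSON serialization; ``pixel_counts`` keeps the exact
    integer ledger (roi = uncovered + covered_single + covered_multi).
    """

    delta_o_percent: float
    delta_z_percent: float
    n_pulses: int
    angle_deg: float
    threshold_pr: float
    uncovered_mask: np.ndarray
    overlap_mask: np.ndarray
    pixel_counts: dict[str, int]
    config_echo: dict

    def __post_init__(self) -> None:
        for name in ("delta_o_percent", "delta_z_percent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} = {v} outside [0, 100]")
        pc = self.pixel_counts
        if pc and pc["roi"] != (
            pc["uncovered"] + pc["covered_single"] + pc["covered_multi"]
        ):
            raise ValueError("pixel ledger does not close")


def coverage_count(
    pulses: list[PulseArea], shape: tuple[int, int]
) -> np.ndarray:
    """Integer per-pixel count of covering pulse footprints."""
    count = np.zeros(shape, dtype=np.int32)
    for p in pulses:
        count += p.mask
    return count


def build_overlap_mask(
    pulses: list[PulseArea], shape: tuple[int, int]
) -> OverlapMask:
    """Mask of pixels where footprints superimpose (coverage count >= 2)."""
    if not pulses:
        raise ValueError("need at least one pulse")
    return OverlapMask(mask=coverage_count(pulses, shape) >= 2)


def delta_o(
    roi: RoiMask,
    pulses: list[PulseArea],
    overlap: OverlapMask | None = None,
) -> float:
    """Undertreatment error: % of ROI pixels covered by zero footprints.

    ``overlap`` is accepted for symmetry with the pairwise
    inclusion-exclusion formulation (|L_R| - sum_i |L_i| + |L_Z|) but is
    not needed by the count-based computation, which is exact for any
    overlap multiplicity.
    """
    count = coverage_count(pulses, roi.mask.shape)
    uncovered = roi.mask & (count == 0)
    return 100.0 * int(uncovered.sum()) / roi.n_pixels


def delta_z(roi: RoiMask, overlap: OverlapMask) -> float:
    """Double-dose error: % of ROI pixels lying in the overlap mask."""
    inside = overlap.mask & roi.mask
    return 100.0 * int(inside.sum()) / roi.n_pixels


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def detect_pulses(img: ThermalImage, config: RunConfig | None = None):
    """Run the geometric stages of the pipeline.

    Returns ``(roi, stack, angle_deg, pulses)``: the treated-region mask,
    the intermediate ROI-stage images, the recovered grid angle and the
    fitted square footprints.  Useful when the pulse geometry itself is
    the quantity of interest rather than the coverage errors.
    """
    config = config or RunConfig()
    with _stage("roi"):
        roi, stack = extract_roi(img, config)
    with _stage("edges"):
        edges = canny_edges(
            stack.l_med,
            roi,
            low=config.canny_low,
            high=config.canny_high,
            sigma=config.canny_sigma,
        )
    with _stage("angle"):
        sino = radon_transform(edges, config.radon_angle_step_deg)
        angle = estimate_grid_angle(sino)
    with _stage("detrend"):
        detrended = remove_constant_component(
            stack.l_med, roi, window_px=config.detrend_window_px
        )
    with _stage("watershed"):
        labels = watershed_pulses(detrended, roi, h_maxima_c=config.h_maxima_c)
    with _stage("fit"):
        support = binarize(stack.l_med - stack.background_c, stack.threshold_pr)
        support &= roi.mask
        pulses = fit_squares(
            labels,
            angle,
            intensity=detrended,
            support=support,
            area_bounds=config.area_bounds,
        )
    return roi, stack, angle, pulses


def analyze_image(img: ThermalImage, config: RunConfig | None = None) -> CoverageReport:
    """Full two-stage analysis of one thermogram.

    Stage one extracts the treated region; stage two recovers the grid
    angle (Canny edges -> Radon transform -> sharpest-peak angle),
    separates footprints by watershed on the detrended topography, fits a
    shared-size rotated square to each, and computes the two coverage
    errors.  Deterministic for a given input and configuration.
    """
    config = config or RunConfig()
    roi, stack, angle, pulses = detect_pulses(img, config)
    with _stage("coverage"):
        count = coverage_count(pulses, roi.mask.shape)
        overlap = OverlapMask(mask=count >= 2)
        uncovered = roi.mask & (count == 0)
        d_o = 100.0 * int(uncovered.sum()) / roi.n_pixels
        d_z = 100.0 * int((overlap.mask & roi.mask).sum()) / roi.n_pixels
    echo = config.to_dict()
    echo["binarization_threshold_pr"] = stack.threshold_pr
    return CoverageReport(
        delta_o_percent=d_o,
        delta_z_percent=d_z,
        n_pulses=len(pulses),
        angle_deg=angle,
        threshold_pr=stack.threshold_pr,
        uncovered_mask=uncovered,
        overlap_mask=overlap.mask & roi.mask,
        pixel_counts={
            "roi": roi.n_pixels,
            "uncovered": int(uncovered.sum()),
            "covered_single": int((roi.mask & (count == 1)).sum()),
            "covered_multi": int((roi.mask & (count >= 2)).sum()),
        },
        config_echo=echo,
    )


def threshold_sweep(
    img: ThermalImage,
    config: RunConfig,
    pr_values: list[float],
):
    """Sensitivity of the coverage errors to the binarization threshold.

    Re-runs :func:`analyze_image` for each threshold and returns a
    DataFrame with columns (p_r, delta_o_percent, delta_z_percent,
    n_pulses).  The undertreatment error grows almost linearly with the
    threshold on typical scenes, which is why no single threshold can be
    called "correct" and the value used is always reported.  A threshold
    whose analysis fails yields a NaN row rather than aborting the sweep.
    """
    import pandas as pd

    pr_values = [float(p) for p in pr_values]
    if any(b <= a for a, b in zip(pr_values, pr_values[1:])):
        raise ValueError("pr_values must be strictly increasing")
    rows = []
    for p_r in pr_values:
        cfg = dataclasses.replace(config, binarization_threshold_pr=p_r)
        try:
            rep = analyze_image(img, cfg)
            rows.append(
                {
                    "p_r": p_r,
                    "delta_o_percent": rep.delta_o_percent,
                    "delta_z_percent": rep.delta_z_percent,
                    "n_pulses": rep.n_pulses,
                }
            )
        except (StageError, ValueError):
            rows.append(
                {
                    "p_r": p_r,
                    "delta_o_percent": float("nan"),
                    "delta_z_percent": float("nan"),
                    "n_pulses": 0,
                }
            )
    return pd.DataFrame(rows)
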