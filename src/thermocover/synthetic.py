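"""Synthetic thermogram generator with pixel-exact ground truth.

No clinical thermograms ship with this package, so every downstream stage
is exercised on generated scenes that reproduce the structure the
algorithm assumes: a baseline skin temperature near 33 degC, square laser
pulse footprints elevated by about 2.5 degC arranged on an approximately
regular grid rotated by an unknown but shared angle, a mild radial falloff
of temperature from each pulse centre (the fluence of the beam is
bell-shaped, so footprint edges run cooler than centres), a short linear
taper at footprint edges, i.i.d. Gaussian sensor noise, and a first-order
step response in time, T(t) = T0 + dT * (1 - exp(-t / tau)).

Ground truth (per-pulse masks, union, overlap, treated-region mask and the
two coverage errors) is computed by direct pixel counting from the
rendered geometry before noise, so it can serve as an oracle for the
analysis pipeline.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from skimage.draw import polygon2mask

from .geometry import frame_coords, rotated_square_mask
from .io_formats import RunConfig, ThermalImage

__all__ = [
    "SyntheticScene",
    "GroundTruth",
    "WindowVerdict",
    "generate_scene",
    "generate_sequence",
    "check_analysis_window",
    "grid_scene",
]


@dataclasses.dataclass
class SyntheticScene:
    """Description of one synthetic treatment scene.

    ``pulses`` is a list of (center_row, center_col, side_px, angle_deg);
    every pulse must share one angle (the operator applies the laser head
    without rotating it between applications).  ``compose`` controls how
    overlapping pulse fields combine: "max" (default; skin temperature
    saturates rather than doubling under a double dose) or "add".
    ``decay_tau_s`` optionally enables a slow exponential relaxation toward
    baseline for robustness testing; footprints persist for many minutes on
    real skin, so it is off by default.
    """

    shape: tuple[int, int] = (480, 640)
    baseline_temp_c: float = 33.0
    elevation_c: float = 2.5
    pulses: list[tuple[float, float, float, float]] = dataclasses.field(
        default_factory=list
    )
    roi_polygon: list[tuple[float, float]] | None = None
    noise_sd_c: float = 0.05
    tau_s: float = 1.5
    falloff_frac: float = 0.3
    taper_px: float = 1.0
    compose: str = "max"
    decay_tau_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(x) for x in self.shape)  # type: ignore[assignment]
        if self.elevation_c <= 0:
            raise ValueError("elevation_c must be positive")
        if self.noise_sd_c < 0:
            raise ValueError(f"noise_sd_c must be nonnegative, got {self.noise_sd_c}")
        if not 0.0 <= self.falloff_frac < 1.0:
            raise ValueError("falloff_frac must lie in [0, 1)")
        if self.compose not in ("max", "add"):
            raise ValueError(f"unknown compose mode {self.compose!r}")
        angles = {float(p[3]) for p in self.pulses}
        if len(angles) > 1:
            raise ValueError(
                f"all pulses must share one angle, got {sorted(angles)}"
            )
        for p in self.pulses:
            if p[2] < 4:
                raise ValueError(f"pulse side must be >= 4 px, got {p[2]}")

    @property
    def angle_deg(self) -> float:
        """The shared grid angle (0 if the scene has no pulses)."""
        return float(self.pulses[0][3]) if self.pulses else 0.0


@dataclasses.dataclass
class GroundTruth:
    """Pixel-exact truth for one generated scene.

    ``true_delta_o_percent`` / ``true_delta_z_percent`` are None when the
    treated-region mask is empty (the errors are undefined without a
    region to normalise by).
    """

    pulse_masks: list[np.ndarray]
    union_mask: np.ndarray
    overlap_mask: np.ndarray
    roi_mask: np.ndarray
    true_delta_o_percent: float | None
    true_delta_z_percent: float | None
    pixel_counts: dict[str, int]

    def __post_init__(self) -> None:
        if np.any(self.overlap_mask & ~self.union_mask):
            raise ValueError("overlap mask must be a subset of the union mask")
        if np.any(self.union_mask & ~self.roi_mask):
            raise ValueError("union mask must be a subset of the treated-region mask")


@dataclasses.dataclass
class WindowVerdict:
    valid: bool
    reason: str

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.valid


def _pulse_elevation_field(
    shape: tuple[int, int],
    center: tuple[float, float],
    side: float,
    angle: float,
    falloff: float,
    taper: float,
) -> tuple[slice, slice, np.ndarray]:
    """Normalized (0..1) elevation profile of one pulse over its window.

    Inside the square the profile is ``1 - falloff * q`` where ``q`` is the
    Chebyshev distance from the centre normalised so q = 1 at the edge.  A
    linear penumbra ramp of total width ``taper`` pixels is centred on the
    footprint boundary (the spot edge of a soft beam is conventionally the
    half-intensity point of its penumbra, so the ramp straddles the nominal
    edge rather than hanging outside it), descending from the edge level to
    zero.
    """
    half = side / 2.0
    margin = (side * math.sqrt(2)) / 2.0 + taper + 1.0
    rs, cs, u, v = frame_coords(shape, center, angle, margin)
    q = np.maximum(np.abs(u), np.abs(v)) / half
    profile = np.where(q <= 1.0, 1.0 - falloff * q, 0.0)
    if taper > 0:
        edge_level = 1.0 - falloff
        q_lo = 1.0 - (taper / 2.0) / half
        q_hi = 1.0 + (taper / 2.0) / half
        ramp = np.clip(edge_level * (q_hi - q) / (q_hi - q_lo), 0.0, None)
        in_ramp = (q > q_lo) & (q <= q_hi)
        profile[in_ramp] = ramp[in_ramp]
    return rs, cs, profile


def _check_in_frame(scene: SyntheticScene) -> None:
    from .geometry import square_corners

    rows, cols = scene.shape
    for r0, c0, side, angle in scene.pulses:
        corners = square_corners((r0, c0), side, angle)
        if (
            corners[:, 0].min() < 0
            or corners[:, 0].max() > rows - 1
            or corners[:, 1].min() < 0
            or corners[:, 1].max() > cols - 1
        ):
            raise ValueError(
                f"pulse at ({r0:.1f}, {c0:.1f}) extends outside the "
                f"{rows}x{cols} frame"
            )


def _render(scene: SyntheticScene) -> tuple[np.ndarray, GroundTruth]:
    rows, cols = scene.shape
    elev = np.zeros((rows, cols), dtype=float)
    pulse_masks: list[np.ndarray] = []
    count = np.zeros((rows, cols), dtype=np.int32)
    for r0, c0, side, angle in scene.pulses:
        mask = rotated_square_mask(scene.shape, (r0, c0), side, angle)
        pulse_masks.append(mask)
        count += mask
        rs, cs, profile = _pulse_elevation_field(
            scene.shape, (r0, c0), side, angle, scene.falloff_frac, scene.taper_px
        )
        window = elev[rs, cs]
        if scene.compose == "max":
            np.maximum(window, profile, out=window)
        else:
            window += profile
        elev[rs, cs] = window
    elev *= scene.elevation_c

    union = count >= 1
    overlap = count >= 2
    if scene.roi_polygon is not None:
        roi = polygon2mask(scene.shape, np.asarray(scene.roi_polygon, dtype=float))
        roi |= union  # the treated field contains every treated pixel
    else:
        roi = union.copy()

    n_roi = int(roi.sum())
    n_uncovered = int((roi & (count == 0)).sum())
    n_overlap = int((roi & overlap).sum())
    n_single = int((roi & (count == 1)).sum())
    if n_roi > 0:
        delta_o = 100.0 * n_uncovered / n_roi
        delta_z = 100.0 * n_overlap / n_roi
    else:
        delta_o = delta_z = None
    truth = GroundTruth(
        pulse_masks=pulse_masks,
        union_mask=union,
        overlap_mask=overlap,
        roi_mask=roi,
        true_delta_o_percent=delta_o,
        true_delta_z_percent=delta_z,
        pixel_counts={
            "roi": n_roi,
            "uncovered": n_uncovered,
            "covered_single": n_single,
            "covered_multi": n_overlap,
        },
    )
    return elev, truth


def generate_scene(scene: SyntheticScene) -> tuple[ThermalImage, GroundTruth]:
    """Render a steady-state thermogram and its ground truth.

    Returns ``(image, truth)``.  The image is baseline + the composed pulse
    elevation field + Gaussian noise of sd ``noise_sd_c``; the ground-truth
    masks reflect the rendered square geometry before noise.  Generation is
    reproducible bit for bit for a fixed seed.
    """
    _check_in_frame(scene)
    elev, truth = _render(scene)
    rng = np.random.default_rng(scene.seed)
    values = scene.baseline_temp_c + elev
    if scene.noise_sd_c > 0:
        values = values + rng.normal(0.0, scene.noise_sd_c, size=values.shape)
    return ThermalImage(values=values), truth  # type: ignore[return-value]


def generate_sequence(
    scene: SyntheticScene, frame_times_s: list[float]
) -> list[ThermalImage]:
    """Render a frame sequence following the first-order step response.

    Pulse pixels follow ``T(t) = T0 + dT * (1 - exp(-t / tau))`` so the
    response is monotone nondecreasing in time with asymptote
    ``baseline + elevation`` (unless the optional slow decay is enabled).
    Noise is drawn independently per frame.
    """
    times = [float(t) for t in frame_times_s]
    if any(t < 0 for t in times):
        raise ValueError("frame times must be nonnegative")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("frame times must be strictly increasing")
    if scene.tau_s <= 0:
        raise ValueError(f"tau_s must be positive, got {scene.tau_s}")
    _check_in_frame(scene)
    elev, _ = _render(scene)
    rng = np.random.default_rng(scene.seed)
    frames = []
    for t in times:
        rise = 1.0 - math.exp(-t / scene.tau_s)
        if scene.decay_tau_s is not None:
            rise *= math.exp(-t / scene.decay_tau_s)
        values = scene.baseline_temp_c + rise * elev
        if scene.noise_sd_c > 0:
            values = values + rng.normal(0.0, scene.noise_sd_c, size=values.shape)
        frames.append(ThermalImage(values=values, timestamp_s=t))
    return frames


def check_analysis_window(
    t_since_last_pulse_s: float, config: RunConfig | None = None
) -> WindowVerdict:
    """Is a frame acquired ``t`` seconds after the last pulse analyzable?

    Too early and the skin has not reached its elevated steady state; too
    late and thermoregulation starts to blur the footprints.  The default
    window is the closed interval [10 s, 180 s].
    """
    if t_since_last_pulse_s < 0:
        raise ValueError("time since last pulse must be nonnegative")
    lo, hi = (config or RunConfig()).analysis_window_s
    if t_since_last_pulse_s < lo:
        return WindowVerdict(False, "before thermal steady state")
    if t_since_last_pulse_s > hi:
        return WindowVerdict(False, "footprints blurred by thermoregulation")
    return WindowVerdict(True, "within analysis window")


def grid_scene(
    n_rows: int = 4,
    n_cols: int = 5,
    side_px: float = 40.0,
    gap_px: float = 2.0,
    angle_deg: float = 0.0,
    shape: tuple[int, int] = (480, 640),
    center: tuple[float, float] | None = None,
    dropout: tuple[tuple[int, int], ...] = (),
    shifts: dict[tuple[int, int], tuple[float, float]] | None = None,
    jitter_px: float = 0.0,
    seed: int = 0,
    **scene_kwargs,
) -> SyntheticScene:
    """Build a regular rotated grid of pulses with a matching region polygon.

    ``dropout`` lists (i, j) grid positions left untreated (they create
    undertreated holes and hence a nonzero delta_o by construction);
    ``shifts`` maps grid positions to (du, dv) displacements in the grid
    frame (used to create controlled overlaps); ``jitter_px`` adds uniform
    placement noise drawn from the scene seed.  The treated-region polygon
    is the rotated rectangle bounding the nominal footprint extents (plus
    the jitter amplitude when jitter is enabled).
    """
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    pitch = side_px + gap_px
    rng = np.random.default_rng(seed)
    a = math.radians(angle_deg)
    cos_a, sin_a = math.cos(a), math.sin(a)
    shifts = shifts or {}

    pulses = []
    for i in range(n_rows):
        for j in range(n_cols):
            if (i, j) in dropout:
                continue
            # grid-frame coordinates: u along columns of the grid, v along rows
            u = (j - (n_cols - 1) / 2.0) * pitch
            v = (i - (n_rows - 1) / 2.0) * pitch
            du, dv = shifts.get((i, j), (0.0, 0.0))
            u += du
            v += dv
            if jitter_px > 0:
                u += rng.uniform(-jitter_px, jitter_px)
                v += rng.uniform(-jitter_px, jitter_px)
            dc = u * cos_a - v * sin_a
            dr = u * sin_a + v * cos_a
            pulses.append((center[0] + dr, center[1] + dc, side_px, angle_deg))

    margin = 0.5 + jitter_px
    u_ext = (n_cols - 1) / 2.0 * pitch + side_px / 2.0 + margin
    v_ext = (n_rows - 1) / 2.0 * pitch + side_px / 2.0 + margin
    polygon = []
    for u, v in ((-u_ext, -v_ext), (u_ext, -v_ext), (u_ext, v_ext), (-u_ext, v_ext)):
        dc = u * cos_a - v * sin_a
        dr = u * sin_a + v * cos_a
        polygon.append((center[0] + dr, center[1] + dc))

    return SyntheticScene(
        shape=shape,
        pulses=pulses,
        roi_polygon=polygon,
        seed=seed,
        **scene_kwargs,
    )
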