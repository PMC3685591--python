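"""Temperature-matrix I/O, run configuration and report serialization.

Thermal images are plain 2-D matrices of skin-surface temperature in
degrees Celsius, indexed (m, n) = (row, column).  Two interchange formats
are supported: headerless CSV (full double precision, lossless) and
single-channel 32-bit float TIFF.  Loading never resamples: the
preprocessing stage owns upsampling.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
import warnings
from typing import TYPE_CHECKING, Any

import numpy as np
import tifffile
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .coverage import CoverageReport

__all__ = [
    "ThermalImage",
    "RunConfig",
    "read_thermal_image",
    "write_thermal_image",
    "write_report",
    "read_report",
    "rle_encode",
    "rle_decode",
]

#: plausible physiological/thermal band for validated images, in degC
TEMP_MIN_C = 0.0
TEMP_MAX_C = 60.0
MIN_DIM_PX = 8


@dataclasses.dataclass
class ThermalImage:
    """A 2-D matrix of skin temperatures in degC with optional metadata.

    ``values[m, n]`` follows the (row, column) convention.  Validation
    enforces finiteness, a minimum frame size and a plausible temperature
    band; out-of-band data indicate a calibration or parsing problem
    upstream and are rejected with the offending extremum named.
    """

    values: np.ndarray
    pixel_pitch_um: float | None = None
    timestamp_s: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(
                f"thermal image must be 2-D, got {self.values.ndim} dimensions"
            )
        if min(self.values.shape) < MIN_DIM_PX:
            raise ValueError(
                f"thermal image must be at least {MIN_DIM_PX}x{MIN_DIM_PX} px, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("thermal image contains non-finite values")
        lo = float(self.values.min())
        hi = float(self.values.max())
        if lo < TEMP_MIN_C or hi > TEMP_MAX_C:
            extremum = lo if lo < TEMP_MIN_C else hi
            raise ValueError(
                f"temperature {extremum:.3f} degC outside plausible band "
                f"[{TEMP_MIN_C}, {TEMP_MAX_C}] degC"
            )

    @property
    def height_px(self) -> int:
        return self.values.shape[0]

    @property
    def width_px(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclasses.dataclass
class RunConfig:
    """Algorithm parameters for one analysis run.

    ``binarization_threshold_pr`` is a temperature offset in degC above the
    pre-treatment skin background; ``None`` selects it automatically as 40%
    of the robust elevated range above the background level (the choice is
    recorded in the report).  ``se_radius_px`` sets the flat square
    structuring element (side ``2r + 1``) used to globalize the treated
    field; a practical rule is just over half of (pulse side + 2 * gap), see
    :meth:`for_pulse_side`.
    """

    binarization_threshold_pr: float | None = None
    se_radius_px: int = 23
    canny_low: float = 0.1
    canny_high: float = 0.3
    canny_sigma: float = 2.0
    radon_angle_step_deg: float = 1.0
    upsample_to: tuple[int, int] = (480, 640)
    median_mask: tuple[int, int] = (3, 3)
    analysis_window_s: tuple[float, float] = (10.0, 180.0)
    # morphology used to globalize the treated field into one cluster:
    # "close" fills the cool inter-pulse gaps (default), "open" applies the
    # anti-extensive operator instead (see docs/methods.md).
    roi_morphology: str = "close"
    # reference subtracted to form the difference image: "background"
    # (scene-wide robust background level) or "median" (the median-filtered
    # image itself).
    difference_reference: str = "background"
    difference_polarity: str = "signed"  # or "absolute"
    background_percentile: float = 50.0
    h_maxima_c: float = 0.3
    connectivity: int = 2
    # None derives the background window from the ROI extent at run time
    detrend_window_px: int | None = None
    area_bounds: tuple[float, float] = (0.25, 4.0)

    def __post_init__(self) -> None:
        self.upsample_to = tuple(int(x) for x in self.upsample_to)  # type: ignore[assignment]
        self.median_mask = tuple(int(x) for x in self.median_mask)  # type: ignore[assignment]
        self.analysis_window_s = tuple(float(x) for x in self.analysis_window_s)  # type: ignore[assignment]
        self.area_bounds = tuple(float(x) for x in self.area_bounds)  # type: ignore[assignment]
        lo, hi = self.analysis_window_s
        if not lo < hi:
            raise ValueError(f"analysis window requires min < max, got ({lo}, {hi})")
        for name in ("se_radius_px", "canny_sigma", "radon_angle_step_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(x <= 0 for x in self.upsample_to) or any(x <= 0 for x in self.median_mask):
            raise ValueError("sizes must be positive")
        if self.roi_morphology not in ("close", "open"):
            raise ValueError(f"unknown roi_morphology {self.roi_morphology!r}")
        if self.difference_reference not in ("background", "median"):
            raise ValueError(f"unknown difference_reference {self.difference_reference!r}")
        if self.difference_polarity not in ("signed", "absolute"):
            raise ValueError(f"unknown difference_polarity {self.difference_polarity!r}")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-neighbour) or 2 (8-neighbour)")
        if not math.isclose(90.0 / self.radon_angle_step_deg,
                            round(90.0 / self.radon_angle_step_deg)):
            warnings.warn(
                f"radon_angle_step_deg={self.radon_angle_step_deg} does not divide "
                "90 degrees exactly; the sampled angle grid will not close",
                stacklevel=2,
            )

    @classmethod
    def for_pulse_side(
        cls,
        side_px: float,
        gap_px: float = 2.0,
        shape: tuple[int, int] | None = None,
        **overrides: Any,
    ) -> "RunConfig":
        """Config tuned to an expected pulse footprint size.

        The structuring element must be able to fill an untreated hole the
        size of one missed pulse (side + 2 * gap), so the radius defaults to
        ``ceil(0.55 * (side_px + 2 * gap_px))``.
        """
        se = int(math.ceil(0.55 * (side_px + 2.0 * gap_px)))
        kwargs: dict[str, Any] = {"se_radius_px": se}
        if shape is not None:
            kwargs["upsample_to"] = tuple(shape)
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("upsample_to", "median_mask", "analysis_window_s", "area_bounds"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "RunConfig":
        """Load a YAML or JSON configuration file mirroring the field names."""
        text = pathlib.Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls(**data)


def _infer_format(path: pathlib.Path, format: str | None) -> str:
    if format is not None:
        if format not in ("csv", "tiff"):
            raise ValueError(f"unknown format {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_thermal_image(
    path: str | pathlib.Path, format: str | None = None
) -> ThermalImage:
    """Read a temperature matrix from headerless CSV or float TIFF.

    Row-major orientation is preserved and no rescaling is applied.  The
    result is validated (finite, within [0, 60] degC, at least 8x8 px).
    """
    path = pathlib.Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "csv":
        try:
            values = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"could not parse {path} as a numeric CSV grid: {exc}")
    else:
        values = np.asarray(tifffile.imread(path))
        if values.ndim != 2:
            raise ValueError(
                f"{path} is not a single-channel 2-D TIFF (shape {values.shape})"
            )
        if not np.issubdtype(values.dtype, np.floating):
            raise ValueError(f"{path} does not hold float temperatures ({values.dtype})")
    return ThermalImage(values=values)


def write_thermal_image(
    img: ThermalImage, path: str | pathlib.Path, format: str | None = None
) -> None:
    """Write a temperature matrix as CSV (lossless) or 32-bit float TIFF."""
    path = pathlib.Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        np.savetxt(path, img.values, delimiter=",", fmt="%.17g")
    else:
        tifffile.imwrite(path, img.values.astype(np.float32))


# --- run-length encoding for binary masks in JSON reports -----------------


def rle_encode(mask: np.ndarray) -> str:
    """Run-length encode a boolean matrix as ``"RxC:n0 n1 n2 ..."``.

    Runs alternate starting with the number of leading False pixels in
    row-major order; the trailing run may be omitted implicitly (it is
    written explicitly here for simplicity).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    flat = mask.ravel()
    if flat.size == 0:
        return f"{mask.shape[0]}x{mask.shape[1]}:"
    change = np.flatnonzero(np.diff(flat))
    bounds = np.concatenate(([0], change + 1, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return f"{mask.shape[0]}x{mask.shape[1]}:" + " ".join(str(r) for r in runs)


def rle_decode(text: str) -> np.ndarray:
    header, _, body = text.partition(":")
    rows, _, cols = header.partition("x")
    shape = (int(rows), int(cols))
    runs = [int(tok) for tok in body.split()] if body.strip() else []
    flat = np.zeros(shape[0] * shape[1], dtype=bool)
    pos = 0
    value = False
    for run in runs:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    if pos != flat.size:
        raise ValueError(f"run lengths sum to {pos}, expected {flat.size}")
    return flat.reshape(shape)


def report_to_dict(report: "CoverageReport") -> dict[str, Any]:
    """JSON-ready dictionary for a coverage report (deterministic layout)."""
    return {
        "schema": "thermocover-report-1",
        "delta_o_percent": round(float(report.delta_o_percent), 2),
        "delta_z_percent": round(float(report.delta_z_percent), 2),
        "n_pulses": int(report.n_pulses),
        "angle_deg": round(float(report.angle_deg), 4),
        "threshold_pr": round(float(report.threshold_pr), 6),
        "pixel_counts": {k: int(v) for k, v in sorted(report.pixel_counts.items())},
        "uncovered_mask_rle": rle_encode(report.uncovered_mask),
        "overlap_mask_rle": rle_encode(report.overlap_mask),
        "config": report.config_echo,
    }


def write_report(report: "CoverageReport", path: str | pathlib.Path) -> None:
    """Serialize a coverage report to JSON with run-length-encoded masks.

    The byte layout is deterministic (sorted keys, fixed rounding), so
    write -> read -> write reproduces the file exactly.
    """
    payload = report_to_dict(report)
    text = json.dumps(payload, sort_keys=True, indent=2) + "\n"
    pathlib.Path(path).write_text(text)


def read_report(path: str | pathlib.Path) -> "CoverageReport":
    from .coverage import CoverageReport

    data = json.loads(pathlib.Path(path).read_text())
    return CoverageReport(
        delta_o_percent=data["delta_o_percent"],
        delta_z_percent=data["delta_z_percent"],
        n_pulses=data["n_pulses"],
        angle_deg=data["angle_deg"],
        threshold_pr=data["threshold_pr"],
        uncovered_mask=rle_decode(data["uncovered_mask_rle"]),
        overlap_mask=rle_decode(data["overlap_mask_rle"]),
        pixel_counts=dict(data["pixel_counts"]),
        config_echo=data["config"],
    )
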