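"""Image and result I/O, coordinate conventions, shared types and errors.

Coordinate convention (used everywhere in this package): ``x`` is the
column index and ``y`` the row index, both 0-based, with pixel centers at
integer coordinates.  A point ``(x, y)`` therefore addresses
``pixels[int(round(y)), int(round(x))]``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DetectionError",
    "GrayImage",
    "BinaryImage",
    "DetectionResult",
    "load_image",
    "rgb_to_gray",
    "write_result",
    "result_to_dict",
    "result_to_csv_row",
    "CSV_HEADER",
]

MIN_SIDE = 8


class DetectionError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class GrayImage:
    """Single-channel image with intensities in [0, 255].

    ``pixels`` may be integer (typically ``uint8``) or floating point; float
    pixels are accepted so that exact, unquantized synthetic inputs can flow
    through the fitting stages.
    """

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {px.shape}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ValueError(f"image too small: {px.shape} (min side {MIN_SIDE})")
        if px.size == 0:
            raise ValueError("zero-size image")
        lo, hi = float(px.min()), float(px.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities outside [0, 255]: min={lo}, max={hi}")
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def as_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64, copy=False)


@dataclass(frozen=True)
class BinaryImage:
    """H×W grid of {0, 1} with a label stating what 1 means."""

    pixels: np.ndarray
    foreground_meaning: str = "foreground"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {px.shape}")
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("binary image must contain only 0/1")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class DetectionResult:
    """Outcome of the full detector on one image.

    ``pupil_center`` is the fitted ellipse center when the pupil path
    succeeded, otherwise ``None`` with ``failure`` naming the failed stage.
    ``glints`` holds the per-glint Gaussian fits (possibly empty).
    """

    pupil_center: Optional[tuple] = None
    pupil_ellipse: Optional[object] = None  # tls_ellipse.EllipseParams
    glints: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    failure: Optional[str] = None


# --------------------------------------------------------------------------
# loading


# ITU-R BT.601 luma weights; rounding is floor(x + 0.5) ("round half up").
_LUMA = np.array([0.299, 0.587, 0.114])


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Luma conversion of an H×W×3 (or ×4, alpha ignored) array, round half up."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError(f"expected H×W×3 color array, got shape {rgb.shape}")
    luma = rgb[:, :, :3] @ _LUMA
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def load_image(path) -> GrayImage:
    """Read an 8-bit PNG/BMP/TIFF image; color inputs are luma-converted."""
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"unreadable image file {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = rgb_to_gray(arr)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.floor(arr.astype(np.float64) + 0.5), 0, 255).astype(np.uint8)
    return GrayImage(arr)


# --------------------------------------------------------------------------
# result serialization

MAX_GLINTS_CSV = 4

CSV_HEADER = (
    ["image", "pupil_x", "pupil_y"]
    + [f"glint{i}_{ax}" for i in range(1, MAX_GLINTS_CSV + 1) for ax in ("x", "y")]
)


def _fmt(v) -> str:
    return "NA" if v is None else f"{v:.2f}"


def result_to_dict(result: DetectionResult) -> dict:
    """JSON-ready nested representation (schema documented in the README)."""
    ellipse = None
    if result.pupil_ellipse is not None:
        e = result.pupil_ellipse
        ellipse = {"A": e.a, "B": e.b, "C": e.c, "D": e.d, "E": e.e, "F": e.f}
    glints = [
        {
            "id": g.region_id,
            "center": [g.center[0], g.center[1]],
            "sigma": [g.sigma[0], g.sigma[1]],
            "amplitude": g.amplitude,
        }
        for g in result.glints
    ]
    return {
        "pupil_center": list(result.pupil_center) if result.pupil_center else None,
        "pupil_ellipse": ellipse,
        "glints": glints,
        "failure": result.failure,
        "diagnostics": _jsonable(result.diagnostics),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def result_to_csv_row(result: DetectionResult, image_name: str = "") -> list:
    """Flat CSV row: pupil x,y then up to 4 glint centers, 2-decimal floats."""
    row = [image_name]
    if result.pupil_center is not None:
        row += [_fmt(result.pupil_center[0]), _fmt(result.pupil_center[1])]
    else:
        row += ["NA", "NA"]
    for i in range(MAX_GLINTS_CSV):
        if i < len(result.glints):
            g = result.glints[i]
            row += [_fmt(g.center[0]), _fmt(g.center[1])]
        else:
            row += ["NA", "NA"]
    return row


def write_result(result: DetectionResult, path, format: str = "json",
                 image_name: str = "") -> None:
    path = Path(path)
    if format == "json":
        try:
            path.write_text(json.dumps(result_to_dict(result), indent=2))
        except OSError as exc:
            raise IOError(f"cannot write {path}: {exc}") from exc
    elif format == "csv":
        try:
            with open(path, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(CSV_HEADER)
                w.writerow(result_to_csv_row(result, image_name))
        except OSError as exc:
            raise IOError(f"cannot write {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown format: {format!r}")


def write_batch_csv(rows: Sequence[Sequence], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        w.writerows(rows)
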