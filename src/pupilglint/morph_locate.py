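"""Morphological cleanup of the pupil binary image and rough localization.

Opening with a ~0.3*T1 square element removes thin eyelash remnants, a
subsequent closing with a ~0.7*T1 element fills glint holes inside the
pupil blob.  Column/row foreground-count projections then give the rough
pupil box (l1..l4), center op' = (l1 + l2/2, l3 + l4/2) and radius
rp' = (l2 + l4)/4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import BinaryImage, DetectionError

__all__ = [
    "StructuringElement",
    "RoughPupil",
    "element_from_threshold",
    "open_close",
    "project",
    "rough_pupil",
]


@dataclass(frozen=True)
class StructuringElement:
    """Square structuring element.  Odd size >= 3 for the pupil path;
    size 2 is allowed only for the glint path."""

    size: int

    def __post_init__(self):
        if self.size == 2:
            return
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(
                f"element size must be odd and >= 3 (or exactly 2), got {self.size}"
            )

    @property
    def footprint(self) -> np.ndarray:
        return np.ones((self.size, self.size), dtype=bool)


@dataclass(frozen=True)
class RoughPupil:
    """Rough pupil box from projections: l1/l3 margins, l2/l4 extents."""

    l1: int  # first column of the box
    l2: int  # box width (columns)
    l3: int  # first row of the box
    l4: int  # box height (rows)

    def __post_init__(self):
        if self.l2 <= 0 or self.l4 <= 0:
            raise ValueError("empty rough-pupil box")
        if self.l1 < 0 or self.l3 < 0:
            raise ValueError("box outside image")

    @property
    def center_rough(self) -> tuple:
        return (self.l1 + self.l2 / 2.0, self.l3 + self.l4 / 2.0)

    @property
    def radius_rough(self) -> float:
        return (self.l2 + self.l4) / 4.0


def element_from_threshold(t1: int, factor: float) -> StructuringElement:
    """size = round(factor*T1), raised to the nearest odd integer >= 3."""
    if t1 < 1:
        raise ValueError(f"T1 must be >= 1, got {t1}")
    size = int(np.floor(factor * t1 + 0.5))
    if size % 2 == 0:
        size += 1
    size = max(size, 3)
    return StructuringElement(size)


def open_close(binary: BinaryImage, open_size: int, close_size: int) -> BinaryImage:
    """Opening then closing with square elements; borders pad as background."""
    h, w = binary.pixels.shape
    for size in (open_size, close_size):
        StructuringElement(size)
        if size > min(h, w):
            raise ValueError(f"element size {size} exceeds image {binary.pixels.shape}")
    fg = binary.pixels.astype(bool)
    opened = ndimage.binary_opening(fg, structure=np.ones((open_size, open_size), bool))
    closed = ndimage.binary_closing(opened, structure=np.ones((close_size, close_size), bool))
    return BinaryImage(closed.astype(np.uint8), foreground_meaning=binary.foreground_meaning)


def project(binary: BinaryImage):
    """Per-column and per-row foreground counts."""
    px = binary.pixels
    return px.sum(axis=0).astype(np.int64), px.sum(axis=1).astype(np.int64)


def _longest_run(profile: np.ndarray):
    """(start, length) of the longest contiguous run of positive entries."""
    positive = np.asarray(profile) > 0
    if not positive.any():
        return None
    padded = np.concatenate(([0], positive.astype(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    lengths = ends - starts
    k = int(np.argmax(lengths))  # first longest run on ties
    return int(starts[k]), int(lengths[k])


def rough_pupil(x_profile: np.ndarray, y_profile: np.ndarray) -> RoughPupil:
    """Rough pupil box from the longest contiguous positive run per axis."""
    run_x = _longest_run(x_profile)
    run_y = _longest_run(y_profile)
    if run_x is None or run_y is None:
        raise DetectionError("rough_pupil", "no pupil candidate: empty projections")
    l1, l2 = run_x
    l3, l4 = run_y
    return RoughPupil(l1=l1, l2=l2, l3=l3, l4=l4)
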