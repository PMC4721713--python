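"""Circular ring rays location (CRRL) of pupil boundary points.

36 rays (10 degrees apart) are cast across an annulus [0.5*rp', 1.5*rp']
around the rough pupil center.  Along each ray the Sobel gradient amplitude
is sampled by bilinear interpolation; contiguous supra-threshold samples
form clusters.  A ray whose cluster count differs from one is interference
(glint or reflection straddling the contour) and contributes nothing; a
clean ray contributes its cluster's maximum-amplitude sample, refined to
subpixel position by a cubic-spline argmax along the ray.

Thresholds derive from delta = T2 - T1 of the trimodal Otsu stage: boundary
points must exceed ``delta_coeff * delta_scale * delta`` and interference
counting uses the more sensitive ``count_coeff * delta_scale * delta``.
``delta_scale`` maps the intensity-domain quantity onto the gradient
amplitude of an optically blurred edge (a hard step of height s yields
amplitude s with the 1/4-normalized Sobel used here; realistic blur lowers
the peak well below the raw contrast).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .core_io import DetectionError, GrayImage
from .morph_locate import RoughPupil
from .trimodal_otsu import ThresholdPair

__all__ = [
    "GradientField",
    "Ray",
    "BoundaryPoint",
    "CrrlParams",
    "gradient_field",
    "cast_rays",
    "detect_on_ray",
    "eliminate_interference",
    "subpixel_refine",
    "collect_boundary",
]

MIN_BOUNDARY_POINTS = 6


@dataclass(frozen=True)
class GradientField:
    """Sobel partial derivatives and gradient amplitude of an image."""

    gx: np.ndarray
    gy: np.ndarray
    amplitude: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.amplitude.shape


@dataclass(frozen=True)
class Ray:
    """One radial ray: ordered samples from inner to outer ring."""

    index: int
    angle_deg: float
    origin: tuple        # rough pupil center (x, y)
    direction: tuple     # unit vector (dx, dy)
    radii: np.ndarray    # sample distances from the origin
    points: np.ndarray   # (n, 2) sample positions (x, y), in-bounds only


@dataclass(frozen=True)
class RayDetection:
    """Per-ray clustering outcome (pre-elimination)."""

    ray: Ray
    candidates: tuple    # (sample_index, x, y, amplitude) per accepted cluster
    n_clusters: int


@dataclass(frozen=True)
class BoundaryPoint:
    x: float
    y: float
    ray_index: int
    amplitude_at_peak: float
    refined: bool = True


@dataclass(frozen=True)
class CrrlParams:
    n_rays: int = 36
    inner_factor: float = 0.5
    outer_factor: float = 1.5
    delta_coeff: float = 1.4
    sample_step: float = 0.5
    # implementation constants (see module docstring); paper-silent
    delta_scale: float = 0.25
    count_coeff: float = 0.8
    max_cluster_width: float = 6.0  # px; wider clusters are interference
    band: bool = False

    def __post_init__(self):
        if not (1.3 <= self.delta_coeff <= 1.5):
            raise ValueError(f"delta_coeff must be in [1.3, 1.5], got {self.delta_coeff}")
        if self.inner_factor >= self.outer_factor:
            raise ValueError("inner_factor must be < outer_factor")
        if self.n_rays < 8 or self.sample_step <= 0:
            raise ValueError("bad ray parameters")

    def select_threshold(self, delta: float) -> float:
        return self.delta_coeff * self.delta_scale * delta

    def count_threshold(self, delta: float) -> float:
        return self.count_coeff * self.delta_scale * delta


def gradient_field(image: GrayImage) -> GradientField:
    """3x3 Sobel gradient, normalized by 1/4 so a unit step yields amplitude 1.

    With the [1,2,1]x[-1,0,1] kernels, a hard intensity step of height s
    produces |g| = s at the pixels flanking the step under this scaling.
    """
    f = image.as_float()
    gx = ndimage.sobel(f, axis=1, mode="nearest") / 4.0
    gy = ndimage.sobel(f, axis=0, mode="nearest") / 4.0
    amplitude = np.hypot(gx, gy)
    return GradientField(gx=gx, gy=gy, amplitude=amplitude)


def cast_rays(rough: RoughPupil, params: CrrlParams, image_shape: tuple) -> list:
    """36 rays at 0, 10, ..., 350 degrees sampled every ``sample_step`` px.

    ``image_shape`` is the (height, width) of the underlying image.  Samples
    falling outside the image are dropped; if the annulus lies fully outside
    the image, a detection failure is raised.
    """
    h, w = image_shape
    cx, cy = rough.center_rough
    rp = rough.radius_rough
    r_in = params.inner_factor * rp
    r_out = params.outer_factor * rp
    n_steps = int(math.ceil((r_out - r_in) / params.sample_step))
    radii = r_in + params.sample_step * np.arange(n_steps + 1)
    radii[-1] = min(radii[-1], r_out)

    rays = []
    total_in_bounds = 0
    for i in range(params.n_rays):
        ang = i * (360.0 / params.n_rays)
        dx, dy = math.cos(math.radians(ang)), math.sin(math.radians(ang))
        xs = cx + radii * dx
        ys = cy + radii * dy
        ok = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
        pts = np.column_stack([xs[ok], ys[ok]])
        total_in_bounds += pts.shape[0]
        rays.append(Ray(index=i, angle_deg=ang, origin=(cx, cy),
                        direction=(dx, dy), radii=radii[ok], points=pts))
    if total_in_bounds == 0:
        raise DetectionError("crrl", "ring annulus lies fully outside the image")
    return rays


def _sample_amplitude(field: GradientField, points: np.ndarray) -> np.ndarray:
    if points.size == 0:
        return np.empty(0)
    coords = np.vstack([points[:, 1], points[:, 0]])  # (row, col)
    return ndimage.map_coordinates(field.amplitude, coords, order=1, mode="nearest")


def _clusters(marked: np.ndarray, max_gap: int = 1) -> list:
    """Index runs of True entries, merging runs separated by <= max_gap."""
    idx = np.flatnonzero(marked)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    return [seg for seg in np.split(idx, breaks + 1)]


def detect_on_ray(ray: Ray, field: GradientField, delta: float,
                  params: CrrlParams) -> RayDetection:
    """Cluster supra-threshold gradient samples along one ray.

    Clusters are counted at the sensitive ``count_threshold``; a cluster
    yields a candidate (its max-amplitude sample) only if that maximum
    reaches the stricter ``select_threshold`` and the cluster is no wider
    than ``max_cluster_width`` px (a clean edge spans a few samples; a glint
    straddling the contour merges with the edge into a much wider cluster).
    With ``band=True`` the selection additionally rejects peaks above
    ``1.5 * delta_scale * delta`` (the literal band reading).
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    amps = _sample_amplitude(field, ray.points)
    if amps.size == 0:
        return RayDetection(ray=ray, candidates=(), n_clusters=0)
    count_thr = params.count_threshold(delta)
    select_thr = params.select_threshold(delta)
    clusters = _clusters(amps >= count_thr)
    candidates = []
    for seg in clusters:
        k = int(seg[np.argmax(amps[seg])])
        peak = float(amps[k])
        if peak < select_thr:
            continue
        if (seg[-1] - seg[0]) * params.sample_step > params.max_cluster_width:
            continue
        if params.band and peak > 1.5 * params.delta_scale * delta:
            continue
        candidates.append((k, float(ray.points[k, 0]), float(ray.points[k, 1]), peak))
    return RayDetection(ray=ray, candidates=tuple(candidates),
                        n_clusters=len(clusters))


def eliminate_interference(per_ray: list) -> list:
    """Keep only rays with exactly one cluster and one accepted candidate.

    A ray crossed by a glint or reflection shows more than one gradient
    cluster; all of its recorded points are discarded.  Fewer than 6
    surviving points cannot constrain the 5 conic coefficients and raises a
    detection failure.
    """
    survivors = []
    for det in per_ray:
        if det.n_clusters == 1 and len(det.candidates) == 1:
            survivors.append((det.ray, det.candidates[0]))
    if len(survivors) < MIN_BOUNDARY_POINTS:
        raise DetectionError(
            "crrl",
            f"insufficient boundary points after interference elimination: "
            f"{len(survivors)} < {MIN_BOUNDARY_POINTS}",
        )
    return survivors


def subpixel_refine(candidate: tuple, ray: Ray, field: GradientField
                    ) -> BoundaryPoint:
    """Refine a candidate to subpixel position along its ray.

    A cubic spline is fitted to the amplitude over candidate +/- 2 samples;
    the refined radius is the spline argmax within that window.  Candidates
    without two neighbors on each side are returned unrefined, flagged.
    """
    k, x, y, peak = candidate
    n = ray.radii.size
    if k < 2 or k > n - 3:
        return BoundaryPoint(x=x, y=y, ray_index=ray.index,
                             amplitude_at_peak=peak, refined=False)
    window = slice(k - 2, k + 3)
    r_win = ray.radii[window]
    a_win = _sample_amplitude(field, ray.points[window])
    spline = CubicSpline(r_win, a_win)
    crit = spline.derivative().roots(extrapolate=False)
    crit = crit[np.isreal(crit)].real if crit.size else crit
    cand_r = np.concatenate([crit, [r_win[0], r_win[-1]]])
    cand_r = cand_r[(cand_r >= r_win[0]) & (cand_r <= r_win[-1])]
    vals = spline(cand_r)
    best = int(np.argmax(vals))
    r_star = float(cand_r[best])
    refined = not (r_star == r_win[0] or r_star == r_win[-1])
    cx, cy = ray.origin
    dx, dy = ray.direction
    return BoundaryPoint(x=cx + r_star * dx, y=cy + r_star * dy,
                         ray_index=ray.index,
                         amplitude_at_peak=float(spline(r_star)),
                         refined=refined)


def collect_boundary(image: GrayImage, rough: RoughPupil,
                     thresholds: ThresholdPair,
                     params: CrrlParams = CrrlParams()) -> list:
    """Full CRRL pass: cast rays, detect, eliminate interference, refine."""
    field = gradient_field(image)
    rays = cast_rays(rough, params, image.pixels.shape)
    per_ray = [detect_on_ray(ray, field, thresholds.delta, params) for ray in rays]
    survivors = eliminate_interference(per_ray)
    return [subpixel_refine(cand, ray, field) for ray, cand in survivors]
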