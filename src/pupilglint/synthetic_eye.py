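"""Seeded renderer of eye-like NIR images with exact ground truth.

Scenes follow the layout the detector expects: a bright skin/sclera
background, a darker iris disk, a dark elliptical pupil (anti-aliased over a
~2 px coverage band), a 2x2 grid of near-saturated Gaussian glints,
optional eyelash-like dark strokes, Gaussian blur and additive sensor
noise.  Rendering is deterministic for a fixed seed, and every structure's
parameters are retained as ground truth for evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.draw import line as draw_line

from .core_io import GrayImage

__all__ = [
    "PupilTruth",
    "IrisTruth",
    "GlintTruth",
    "EyelashStroke",
    "SceneTruth",
    "render",
    "sample_scene",
]

DEFAULT_SIZE = (640, 480)
EDGE_BAND = 2.0  # px, coverage-shaded transition width


@dataclass(frozen=True)
class PupilTruth:
    center: tuple      # (x, y)
    a: float           # semi-axis along the tilt direction
    b: float
    tilt_deg: float
    gray: float

    def radial(self, x, y):
        """Normalized elliptical radius (1.0 on the contour) and its gradient
        magnitude, used for signed-distance shading."""
        phi = math.radians(self.tilt_deg)
        dx = np.asarray(x, float) - self.center[0]
        dy = np.asarray(y, float) - self.center[1]
        u = (dx * math.cos(phi) + dy * math.sin(phi)) / self.a
        v = (-dx * math.sin(phi) + dy * math.cos(phi)) / self.b
        rho = np.hypot(u, v)
        grad = np.hypot(u / self.a, v / self.b) / np.maximum(rho, 1e-9)
        return rho, grad

    def signed_distance(self, x, y):
        """Approximate signed distance to the contour in px (positive inside)."""
        rho, grad = self.radial(x, y)
        return (1.0 - rho) / np.maximum(grad, 1e-12)

    def contour_point(self, t: float) -> tuple:
        phi = math.radians(self.tilt_deg)
        px = self.a * math.cos(t)
        py = self.b * math.sin(t)
        return (
            self.center[0] + px * math.cos(phi) - py * math.sin(phi),
            self.center[1] + px * math.sin(phi) + py * math.cos(phi),
        )


@dataclass(frozen=True)
class IrisTruth:
    center: tuple
    radius: float
    gray: float


@dataclass(frozen=True)
class GlintTruth:
    center: tuple
    sigma_x: float
    sigma_y: float
    amplitude: float   # H; must be near saturation


@dataclass(frozen=True)
class EyelashStroke:
    start: tuple
    end: tuple
    gray: float
    width: int = 1


@dataclass(frozen=True)
class SceneTruth:
    pupil: PupilTruth
    iris: IrisTruth
    background_gray: float
    glints: tuple = ()
    occluders: tuple = ()
    noise_sigma: float = 2.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (self.pupil.gray < self.iris.gray < self.background_gray):
            raise ValueError("need pupil gray < iris gray < background gray")
        for g in self.glints:
            if g.amplitude < 245:
                raise ValueError(f"glint amplitude {g.amplitude} < 245")


def _coverage(signed_distance: np.ndarray, band: float = EDGE_BAND) -> np.ndarray:
    """Fraction of the pixel inside the shape, ramped over ``band`` px."""
    return np.clip(signed_distance / band + 0.5, 0.0, 1.0)


def _check_bounds(truth: SceneTruth, w: int, h: int) -> None:
    cx, cy = truth.pupil.center
    ext = max(truth.pupil.a, truth.pupil.b)
    if not (ext <= cx <= w - 1 - ext and ext <= cy <= h - 1 - ext):
        raise ValueError("pupil ellipse extends outside the image")
    ix, iy = truth.iris.center
    r = truth.iris.radius
    if not (r <= ix <= w - 1 - r and r <= iy <= h - 1 - r):
        raise ValueError("iris disk extends outside the image")
    for g in truth.glints:
        gx, gy = g.center
        if not (0 <= gx <= w - 1 and 0 <= gy <= h - 1):
            raise ValueError("glint center outside the image")


def render(truth: SceneTruth, size: tuple = DEFAULT_SIZE) -> GrayImage:
    """Paint the scene back-to-front, blur, add noise, quantize to 8-bit."""
    w, h = size
    _check_bounds(truth, w, h)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    img = np.full((h, w), float(truth.background_gray))

    ix, iy = truth.iris.center
    d_iris = truth.iris.radius - np.hypot(xx - ix, yy - iy)
    cov = _coverage(d_iris)
    img = img * (1.0 - cov) + truth.iris.gray * cov

    cov = _coverage(truth.pupil.signed_distance(xx, yy))
    img = img * (1.0 - cov) + truth.pupil.gray * cov

    for stroke in truth.occluders:
        _paint_stroke(img, stroke)

    for g in truth.glints:
        gx, gy = g.center
        img += g.amplitude * np.exp(
            -((xx - gx) ** 2 / (2.0 * g.sigma_x ** 2)
              + (yy - gy) ** 2 / (2.0 * g.sigma_y ** 2))
        )

    # optical blur acts on the unclipped radiance; the sensor saturates after
    if truth.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, truth.blur_sigma, mode="nearest")
    img = np.clip(img, 0.0, 255.0)
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        img = img + rng.normal(0.0, truth.noise_sigma, img.shape)

    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return GrayImage(img)


def _paint_stroke(img: np.ndarray, stroke: EyelashStroke) -> None:
    h, w = img.shape
    r0, c0 = int(round(stroke.start[1])), int(round(stroke.start[0]))
    r1, c1 = int(round(stroke.end[1])), int(round(stroke.end[0]))
    rr, cc = draw_line(r0, c0, r1, c1)
    for off in range(stroke.width):
        rs = np.clip(rr, 0, h - 1)
        cs = np.clip(cc + off, 0, w - 1)
        img[rs, cs] = stroke.gray


def truth_to_dict(truth: SceneTruth) -> dict:
    return asdict(truth)


# --------------------------------------------------------------------------
# scene sampling

DIFFICULTIES = ("clean", "occluded", "contour_glint")


def sample_scene(rng_seed: int, difficulty: str = "clean",
                 size: tuple = DEFAULT_SIZE) -> SceneTruth:
    """Draw a random scene with the documented parameter ranges.

    clean:         glints placed on the iris, well clear of the ray annulus;
    occluded:      5-15 eyelash strokes crossing the upper pupil region;
    contour_glint: at least one glint center within 2 px of the pupil
                   contour (the hard interference case).
    """
    if difficulty not in DIFFICULTIES:
        raise ValueError(f"difficulty must be one of {DIFFICULTIES}")
    rng = np.random.default_rng(rng_seed)
    w, h = size

    a = rng.uniform(25.0, 70.0)
    # eccentricity <= 0.6 -> b >= 0.8 a
    b = a * rng.uniform(0.8, 1.0)
    if rng.random() < 0.5:
        a, b = b, a
    tilt = rng.uniform(0.0, 180.0)
    rp_mean = (a + b) / 2.0

    # iris must contain the outer ray ring and the glint grid
    iris_radius = 1.5 * rp_mean + rng.uniform(28.0, 45.0)
    margin = iris_radius + 4.0
    cx = rng.uniform(margin, w - 1 - margin)
    cy = rng.uniform(margin, h - 1 - margin)

    pupil = PupilTruth(center=(cx, cy), a=a, b=b, tilt_deg=tilt,
                       gray=rng.uniform(10.0, 30.0))
    iris = IrisTruth(center=(cx, cy), radius=iris_radius,
                     gray=rng.uniform(100.0, 140.0))
    background = rng.uniform(180.0, 230.0)

    glints = _sample_glints(rng, pupil, rp_mean, difficulty)
    occluders = _sample_occluders(rng, pupil) if difficulty == "occluded" else ()

    return SceneTruth(
        pupil=pupil, iris=iris, background_gray=background,
        glints=tuple(glints), occluders=tuple(occluders),
        noise_sigma=2.0, blur_sigma=1.0, seed=int(rng_seed),
    )


def _sample_glints(rng, pupil: PupilTruth, rp_mean: float, difficulty: str):
    """2x2-style grid of four glints on the iris, outside the ray annulus.

    For ``contour_glint`` one glint is moved onto the pupil contour."""
    cx, cy = pupil.center
    glints = []
    base_angles = np.array([45.0, 135.0, 225.0, 315.0]) + rng.uniform(-8, 8, 4)
    r_g = 1.5 * rp_mean + rng.uniform(12.0, 20.0)
    for ang in base_angles:
        gx = cx + r_g * math.cos(math.radians(ang))
        gy = cy + r_g * math.sin(math.radians(ang))
        glints.append(GlintTruth(
            center=(gx, gy),
            sigma_x=rng.uniform(1.5, 2.5), sigma_y=rng.uniform(1.5, 2.5),
            amplitude=rng.uniform(245.0, 255.0),
        ))
    if difficulty == "contour_glint":
        k = int(rng.integers(0, 4))
        t = rng.uniform(0.0, 2.0 * math.pi)
        px, py = pupil.contour_point(t)
        # radial jitter, keeping the center within 2 px of the contour
        jitter = rng.uniform(-2.0, 2.0)
        nx = (px - cx) / max(math.hypot(px - cx, py - cy), 1e-9)
        ny = (py - cy) / max(math.hypot(px - cx, py - cy), 1e-9)
        g = glints[k]
        # straddling the dark pupil halves the pedestal; a specular highlight
        # is far beyond sensor range, so give it a pre-clip amplitude that
        # still saturates over the pupil side
        glints[k] = GlintTruth(center=(px + jitter * nx, py + jitter * ny),
                               sigma_x=g.sigma_x, sigma_y=g.sigma_y,
                               amplitude=rng.uniform(350.0, 450.0))
    return glints


def _sample_occluders(rng, pupil: PupilTruth):
    """Eyelash-like dark strokes draping over the upper pupil area."""
    cx, cy = pupil.center
    n = int(rng.integers(5, 16))
    strokes = []
    for _ in range(n):
        sx = cx + rng.uniform(-pupil.a, pupil.a)
        sy = cy - pupil.b - rng.uniform(10.0, 40.0)
        ex = sx + rng.uniform(-15.0, 15.0)
        ey = sy + rng.uniform(20.0, pupil.b + 30.0)
        strokes.append(EyelashStroke(
            start=(sx, sy), end=(ex, ey),
            gray=rng.uniform(15.0, 40.0),
            width=int(rng.integers(1, 3)),
        ))
    return strokes
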