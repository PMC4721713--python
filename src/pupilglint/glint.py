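"""Glint (corneal reflection) detection and Gaussian center fitting.

Glints are near-saturated blobs: binarize at a fixed high threshold (240),
clean with a 2x2 opening-closing, and keep 8-connected components within an
area band.  Each region's intensity profile is modeled as a 2-D Gaussian

    I(x, y) = H * exp(-((x-xg)^2 / (2 sx^2) + (y-yg)^2 / (2 sy^2)))

which the log transform turns into the linear model
z = a x^2 + b y^2 + c x + d y + e with a = -1/(2 sx^2), b = -1/(2 sy^2),
c = xg/sx^2, d = yg/sy^2.  The model is solved with the same centered TLS
machinery used for the ellipse fit, and the center follows from
xg = -c/(2a), yg = -d/(2b).

Fits run in region-local coordinates (about the box center) for
conditioning, and exactly-saturated pixels (255) are excluded since their
clipped values bias the log paraboloid.  When the region sits on a bright
pedestal (iris/skin), the pedestal median measured on the fit-window
perimeter is subtracted first so the residual profile is Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import GrayImage
from .morph_locate import open_close
from .trimodal_otsu import binarize
from . import tls_ellipse

__all__ = [
    "GlintRegion",
    "GlintFit",
    "find_regions",
    "gaussian_fit",
    "detect_glints",
]

MIN_FIT_PIXELS = 6

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class GlintRegion:
    """One connected bright component: id, inclusive box and member pixels."""

    id: int
    box: tuple            # (x_min, y_min, x_max, y_max), inclusive
    coords: np.ndarray    # (n, 2) member pixel (x, y)
    intensities: np.ndarray

    @property
    def area(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class GlintFit:
    """Gaussian model of one glint."""

    amplitude: float      # H, peak gray level of the Gaussian component
    center: tuple         # (xg, yg), subpixel
    sigma: tuple          # (sigma_x, sigma_y) in px
    coeffs: tuple         # (a, b, c, d, e) in region-local coordinates
    region_id: int
    n_pixels: int
    diagnostics: dict = field(default_factory=dict, compare=False)


def find_regions(image: GrayImage, threshold: int = 240, min_area: int = 4,
                 max_area: int = 400) -> list:
    """Rough glint regions: fixed-threshold binarization, 2x2 open-close,
    8-connected labeling and an area filter; ids are row-major from 1."""
    binary = binarize(image, threshold, foreground="above")
    cleaned = open_close(binary, open_size=2, close_size=2)
    labels, n = ndimage.label(cleaned.pixels, structure=_EIGHT_CONNECTED)
    regions = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        area = rows.size
        if not (min_area <= area <= max_area):
            continue
        box = (int(cols.min()), int(rows.min()), int(cols.max()), int(rows.max()))
        coords = np.column_stack([cols, rows]).astype(float)
        regions.append((box, coords, image.as_float()[rows, cols]))
    # row-major numbering: top-to-bottom, then left-to-right
    regions.sort(key=lambda r: (r[0][1], r[0][0]))
    return [
        GlintRegion(id=i + 1, box=box, coords=coords, intensities=vals)
        for i, (box, coords, vals) in enumerate(regions)
    ]


def gaussian_fit(region: GlintRegion, image: GrayImage, floor_frac: float = 0.2,
                 halo: int = 2, pedestal_min: float = 5.0):
    """Fit the log-linearized Gaussian over the region and its halo.

    Usable pixels lie in the region box expanded by ``halo``, are not
    exactly saturated (255), and keep intensity >= max(1, floor_frac * max)
    after pedestal subtraction.  Returns ``None`` for regions that are not
    Gaussian-shaped (a >= 0 or b >= 0, or spread wider than the fit
    window), have fewer than 6 usable pixels, or whose fitted center
    escapes the box dilated by 1 px.
    """
    f = image.as_float()
    h, w = f.shape
    x0, y0, x1, y1 = region.box
    xa, ya = max(x0 - halo, 0), max(y0 - halo, 0)
    xb, yb = min(x1 + halo, w - 1), min(y1 + halo, h - 1)
    patch = f[ya:yb + 1, xa:xb + 1]

    # pedestal: median of a perimeter ring far enough out (halo + 4 px) that
    # the Gaussian tail no longer contributes
    bg_halo = halo + 4
    bxa, bya = max(x0 - bg_halo, 0), max(y0 - bg_halo, 0)
    bxb, byb = min(x1 + bg_halo, w - 1), min(y1 + bg_halo, h - 1)
    bg_patch = f[bya:byb + 1, bxa:bxb + 1]
    perim = np.concatenate([bg_patch[0, :], bg_patch[-1, :],
                            bg_patch[1:-1, 0], bg_patch[1:-1, -1]])
    pedestal = float(np.median(perim))
    if pedestal < pedestal_min:
        pedestal = 0.0
    signal = patch - pedestal

    floor = max(1.0, floor_frac * float(signal.max()))
    usable = (signal >= floor) & (patch < 255.0)
    n_usable = int(usable.sum())
    if n_usable < MIN_FIT_PIXELS:
        return None

    rows, cols = np.nonzero(usable)
    # region-local coordinates about the box center for conditioning
    ox = (xa + xb) / 2.0
    oy = (ya + yb) / 2.0
    x = cols + xa - ox
    y = rows + ya - oy
    z = np.log(signal[rows, cols])

    design = np.column_stack([x * x, y * y, x, y])
    means = design.mean(axis=0)
    z_bar = float(z.mean())
    X = design - means
    Z = z - z_bar
    if np.linalg.matrix_rank(X) < 4:
        return None
    tau, info = tls_ellipse.tls_solve(X, Z)
    a, b, c, d = (float(v) for v in tau)
    e = float(z_bar - means @ tau)
    if a >= 0 or b >= 0:
        return None

    xg_l = -c / (2.0 * a)
    yg_l = -d / (2.0 * b)
    xg, yg = xg_l + ox, yg_l + oy
    if not (x0 - 1 <= xg <= x1 + 1 and y0 - 1 <= yg <= y1 + 1):
        return None
    sigma_x = math.sqrt(-1.0 / (2.0 * a))
    sigma_y = math.sqrt(-1.0 / (2.0 * b))
    # plausibility: a glint's spread cannot exceed its fit window
    if max(sigma_x, sigma_y) > min(xb - xa + 1, yb - ya + 1):
        return None
    amplitude = math.exp(e - a * xg_l * xg_l - b * yg_l * yg_l)
    return GlintFit(
        amplitude=amplitude,
        center=(xg, yg),
        sigma=(sigma_x, sigma_y),
        coeffs=(a, b, c, d, e),
        region_id=region.id,
        n_pixels=n_usable,
        diagnostics={"pedestal": pedestal, "tls": info},
    )


def detect_glints(image: GrayImage, threshold: int = 240, min_area: int = 4,
                  max_area: int = 400, floor_frac: float = 0.2,
                  halo: int = 2) -> list:
    """find_regions then gaussian_fit per region; rejected regions dropped."""
    fits = []
    for region in find_regions(image, threshold=threshold, min_area=min_area,
                               max_area=max_area):
        fit = gaussian_fit(region, image, floor_frac=floor_frac, halo=halo)
        if fit is not None:
            fits.append(fit)
    return fits
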