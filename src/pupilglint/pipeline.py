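"""End-to-end detector composing all stages.

Pupil path: 3x3 smoothing -> trimodal Otsu thresholds -> binarize at T1 ->
opening-closing (elements 0.3*T1 / 0.7*T1) -> projection-based rough pupil
-> CRRL boundary points -> TLS ellipse fit -> center.  Glint detection runs
independently on the original, unsmoothed image (smoothing would flatten
the peaks).  Any stage failure produces a result naming the failed stage
with downstream pupil fields absent; glints are still reported.
"""

from __future__ import annotations

from . import crrl, glint, morph_locate, tls_ellipse, trimodal_otsu
from .config import DEFAULTS, _deep_merge
from .core_io import DetectionError, DetectionResult, GrayImage

__all__ = ["detect"]


def detect(image: GrayImage, config: dict = None) -> DetectionResult:
    cfg = _deep_merge(DEFAULTS, config or {})
    result = DetectionResult()
    diag = result.diagnostics

    # glint path (independent of pupil path)
    try:
        result.glints = glint.detect_glints(
            image,
            threshold=cfg["glint"]["threshold"],
            min_area=cfg["glint"]["min_area"],
            max_area=cfg["glint"]["max_area"],
            floor_frac=cfg["glint"]["floor_frac"],
            halo=cfg["glint"]["halo"],
        )
        diag["n_glints"] = len(result.glints)
    except DetectionError as exc:  # pragma: no cover - glint path has no hard failures
        diag["glint_failure"] = str(exc)

    try:
        smoothed = (trimodal_otsu.smooth_3x3(image)
                    if cfg["otsu"]["smooth"] else image)
        hist = trimodal_otsu.histogram(smoothed)
        thresholds = trimodal_otsu.solve_thresholds(
            hist, t1_range=tuple(cfg["otsu"]["t1_range"]),
            t2_max=cfg["otsu"]["t2_max"])
        diag["thresholds"] = {
            "t1": thresholds.t1, "t2": thresholds.t2,
            "delta": thresholds.delta,
            "criterion_g": thresholds.criterion_g,
            "eq6_residuals": thresholds.diagnostics["eq6_residuals"],
        }

        binary = trimodal_otsu.binarize(smoothed, thresholds.t1, foreground="below")
        open_el = morph_locate.element_from_threshold(
            thresholds.t1, cfg["morph"]["open_factor"])
        close_el = morph_locate.element_from_threshold(
            thresholds.t1, cfg["morph"]["close_factor"])
        cleaned = morph_locate.open_close(binary, open_el.size, close_el.size)
        diag["elements"] = {"open": open_el.size, "close": close_el.size}

        x_prof, y_prof = morph_locate.project(cleaned)
        rough = morph_locate.rough_pupil(x_prof, y_prof)
        diag["rough"] = {
            "box": (rough.l1, rough.l2, rough.l3, rough.l4),
            "center": rough.center_rough,
            "radius": rough.radius_rough,
        }

        params = crrl.CrrlParams(
            n_rays=cfg["crrl"]["n_rays"],
            inner_factor=cfg["crrl"]["inner"],
            outer_factor=cfg["crrl"]["outer"],
            delta_coeff=cfg["crrl"]["delta_coeff"],
            sample_step=cfg["crrl"]["step"],
            delta_scale=cfg["crrl"]["delta_scale"],
            count_coeff=cfg["crrl"]["count_coeff"],
            max_cluster_width=cfg["crrl"]["max_width"],
            band=cfg["crrl"]["band"],
        )
        grad_image = smoothed if cfg["crrl"]["use_smoothed"] else image
        points = crrl.collect_boundary(grad_image, rough, thresholds, params)
        diag["n_boundary_points"] = len(points)
        diag["boundary_points"] = [(p.x, p.y) for p in points]

        ellipse = tls_ellipse.fit_ellipse(points,
                                          cond_limit=cfg["fit"]["cond_limit"])
        result.pupil_ellipse = ellipse
        result.pupil_center = tls_ellipse.ellipse_center(ellipse)
        diag["fit"] = ellipse.diagnostics
    except DetectionError as exc:
        result.failure = exc.stage
        diag["failure_message"] = str(exc)

    return result
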