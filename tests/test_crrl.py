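import math

import numpy as np
import pytest

from pupilglint import morph_locate as ml
from pupilglint import trimodal_otsu as ot
from pupilglint.core_io import DetectionError, GrayImage
from pupilglint.crrl import (BoundaryPoint, CrrlParams, Ray, RayDetection,
                             cast_rays, collect_boundary, detect_on_ray,
                             eliminate_interference, gradient_field,
                             subpixel_refine)
from pupilglint.morph_locate import RoughPupil


def make_ray(points, origin=(0.0, 0.0), direction=(1.0, 0.0), index=0):
    points = np.asarray(points, dtype=float)
    radii = np.hypot(points[:, 0] - origin[0], points[:, 1] - origin[1])
    return Ray(index=index, angle_deg=index * 10.0, origin=origin,
               direction=direction, radii=radii, points=points)


class TestGradientField:
    def test_constant_zero(self):
        field = gradient_field(GrayImage(np.full((10, 10), 50, dtype=np.uint8)))
        assert np.all(field.amplitude == 0)

    def test_vertical_step_amplitude_is_step_height(self):
        arr = np.zeros((10, 10), dtype=np.uint8)
        arr[:, 5:] = 100
        field = gradient_field(GrayImage(arr))
        # columns flanking the step carry amplitude == step height
        assert field.amplitude[5, 4] == pytest.approx(100.0)
        assert field.amplitude[5, 5] == pytest.approx(100.0)
        assert field.gx[5, 4] > 0  # brighter to the right

    def test_hand_computed_sobel_patch(self):
        # rows constant, step between columns 1 and 2 of a 3x5 patch
        arr = np.array([[0, 0, 90, 90, 90]] * 3, dtype=np.uint8)
        field = gradient_field(GrayImage(np.pad(arr, 3, mode="edge")))
        # interior pixel at the last 0-column: gx = (4*90)/4 = 90
        assert field.gx[4, 4] == pytest.approx(90.0)
        assert field.gy[4, 4] == pytest.approx(0.0)

    def test_rotated_edge_isotropy(self):
        # linear ramp edges: peak amplitude at 45 degrees within 3% of the
        # axis-aligned value (the analytic edge model is a finite-slope ramp)
        yy, xx = np.mgrid[0:40, 0:40].astype(float)
        slope = 25.0
        vert = np.clip((xx - 12.0) * slope, 0, 100)
        diag = np.clip(((xx + yy) / math.sqrt(2) - 18.0) * slope, 0, 100)
        fv = gradient_field(GrayImage(vert))
        fd = gradient_field(GrayImage(diag))
        assert fd.amplitude.max() == pytest.approx(fv.amplitude.max(), rel=0.03)


class TestCastRays:
    def _rough(self):
        # box chosen so center_rough = (100.5, 100.5), radius_rough = 20.5
        return RoughPupil(l1=80, l2=41, l3=80, l4=41)

    def test_ray0_geometry(self):
        rough = RoughPupil(l1=80, l2=40, l3=80, l4=40)  # center (100,100), rp 20
        rays = cast_rays(rough, CrrlParams(), (480, 640))
        r0 = rays[0]
        assert r0.points[0] == pytest.approx([110.0, 100.0])
        assert r0.points[-1] == pytest.approx([130.0, 100.0])
        assert len(rays) == 36
        assert [r.angle_deg for r in rays] == pytest.approx(
            [10.0 * i for i in range(36)])

    def test_corner_clipping_keeps_36_rays(self):
        rough = RoughPupil(l1=0, l2=30, l3=0, l4=30)
        rays = cast_rays(rough, CrrlParams(), (480, 640))
        assert len(rays) == 36
        for ray in rays:
            if ray.points.size:
                assert ray.points[:, 0].min() >= 0 and ray.points[:, 1].min() >= 0

    def test_sample_count_formula(self):
        rough = self._rough()
        params = CrrlParams()
        rays = cast_rays(rough, params, (480, 640))
        rp = rough.radius_rough
        span = (params.outer_factor - params.inner_factor) * rp
        expected_per_ray = math.ceil(span / params.sample_step) + 1
        assert sum(r.points.shape[0] for r in rays) == 36 * expected_per_ray

    def test_annulus_outside_image_fails(self):
        rough = RoughPupil(l1=2000, l2=40, l3=2000, l4=40)
        with pytest.raises(DetectionError):
            cast_rays(rough, CrrlParams(), (480, 640))


def _edge_image(step_at=60, lo=20, hi=120, shape=(120, 120)):
    arr = np.full(shape, lo, dtype=np.uint8)
    arr[:, step_at:] = hi
    return GrayImage(arr)


class TestDetectOnRay:
    def test_clean_edge_single_cluster(self):
        img = _edge_image()
        field = gradient_field(img)
        xs = np.arange(40.0, 80.0, 0.5)
        ray = make_ray(np.column_stack([xs, np.full_like(xs, 60.0)]),
                       origin=(40.0, 60.0))
        det = detect_on_ray(ray, field, delta=100.0, params=CrrlParams())
        assert det.n_clusters == 1
        assert len(det.candidates) == 1
        assert det.candidates[0][1] == pytest.approx(60.0, abs=1.0)

    def test_flat_region_no_cluster(self):
        img = _edge_image()
        field = gradient_field(img)
        xs = np.arange(5.0, 40.0, 0.5)
        ray = make_ray(np.column_stack([xs, np.full_like(xs, 30.0)]),
                       origin=(5.0, 30.0))
        det = detect_on_ray(ray, field, delta=100.0, params=CrrlParams())
        assert det.n_clusters == 0 and det.candidates == ()

    def test_edge_plus_glint_two_clusters(self):
        arr = np.full((120, 120), 20, dtype=np.uint8)
        arr[:, 60:] = 120
        yy, xx = np.mgrid[0:120, 0:120].astype(float)
        blob = 200.0 * np.exp(-((xx - 45) ** 2 + (yy - 60) ** 2) / (2 * 2.0 ** 2))
        img = GrayImage(np.clip(arr + blob, 0, 255))
        field = gradient_field(img)
        xs = np.arange(30.0, 80.0, 0.5)
        ray = make_ray(np.column_stack([xs, np.full_like(xs, 60.0)]),
                       origin=(30.0, 60.0))
        det = detect_on_ray(ray, field, delta=100.0, params=CrrlParams())
        assert det.n_clusters >= 2

    def test_delta_must_be_positive(self):
        img = _edge_image()
        field = gradient_field(img)
        ray = make_ray([[10.0, 10.0]])
        with pytest.raises(ValueError):
            detect_on_ray(ray, field, delta=0.0, params=CrrlParams())


class TestEliminateInterference:
    def _det(self, n_clusters, n_candidates=None, index=0):
        if n_candidates is None:
            n_candidates = 1 if n_clusters == 1 else n_clusters
        ray = make_ray([[float(index), 0.0]], index=index)
        cands = tuple((0, float(index), 0.0, 50.0) for _ in range(n_candidates))
        return RayDetection(ray=ray, candidates=cands, n_clusters=n_clusters)

    def test_all_clean(self):
        per_ray = [self._det(1, index=i) for i in range(36)]
        assert len(eliminate_interference(per_ray)) == 36

    def test_glint_rays_dropped(self):
        per_ray = [self._det(2 if i < 6 else 1, index=i) for i in range(36)]
        survivors = eliminate_interference(per_ray)
        assert len(survivors) == 30
        assert all(ray.index >= 6 for ray, _ in survivors)

    def test_all_blocked_raises(self):
        per_ray = [self._det(2, index=i) for i in range(36)]
        with pytest.raises(DetectionError):
            eliminate_interference(per_ray)

    def test_five_survivors_insufficient(self):
        per_ray = [self._det(1 if i < 5 else 0, n_candidates=1 if i < 5 else 0,
                             index=i) for i in range(36)]
        with pytest.raises(DetectionError):
            eliminate_interference(per_ray)


class _ProfileField:
    """GradientField stand-in with a prescribed 1-D amplitude profile."""

    def __init__(self, fn, shape=(200, 200)):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        self.amplitude = fn(xx, yy)
        self.gx = np.zeros_like(self.amplitude)
        self.gy = np.zeros_like(self.amplitude)


class TestSubpixelRefine:
    def _ray_along_x(self, y=50.0, x0=38.0, n=15, step=1.0):
        # integer-step samples on a grid row so bilinear sampling returns the
        # analytic profile values exactly
        xs = x0 + step * np.arange(n)
        return make_ray(np.column_stack([xs, np.full(n, y)]), origin=(x0, y))

    def test_peak_on_sample_unchanged(self):
        peak = 45.0  # exactly on a sample
        field = _ProfileField(lambda x, y: 100 * np.exp(-(x - peak) ** 2 / 8.0))
        ray = self._ray_along_x()
        k = int(np.argmax([100 * math.exp(-(p[0] - peak) ** 2 / 8.0)
                           for p in ray.points]))
        cand = (k, ray.points[k, 0], ray.points[k, 1], 100.0)
        bp = subpixel_refine(cand, ray, field)
        assert bp.x == pytest.approx(peak, abs=1e-9)
        assert bp.refined

    def test_offset_peak_recovered(self):
        peak = 45.3  # 0.3 px off the sample grid
        field = _ProfileField(lambda x, y: 100 * np.exp(-(x - peak) ** 2 / 8.0))
        ray = self._ray_along_x()
        amps = 100 * np.exp(-(ray.points[:, 0] - peak) ** 2 / 8.0)
        k = int(np.argmax(amps))
        bp = subpixel_refine((k, ray.points[k, 0], ray.points[k, 1], amps[k]),
                             ray, field)
        # oracle: dense argmax of the same profile
        dense = np.linspace(ray.points[0, 0], ray.points[-1, 0], 200001)
        oracle = dense[np.argmax(100 * np.exp(-(dense - peak) ** 2 / 8.0))]
        assert bp.x == pytest.approx(oracle, abs=0.1)
        assert abs(bp.x - peak) < 0.1

    def test_linear_ramp_clamped_and_flagged(self):
        field = _ProfileField(lambda x, y: x)
        ray = self._ray_along_x()
        k = 10
        bp = subpixel_refine((k, ray.points[k, 0], ray.points[k, 1],
                              float(ray.points[k, 0])), ray, field)
        assert not bp.refined
        assert bp.x == pytest.approx(ray.points[k + 2, 0])  # window end

    def test_too_close_to_ray_end_unrefined(self):
        field = _ProfileField(lambda x, y: x)
        ray = self._ray_along_x()
        bp = subpixel_refine((1, ray.points[1, 0], ray.points[1, 1], 1.0),
                             ray, field)
        assert not bp.refined
        assert bp.x == ray.points[1, 0]


def _pupil_chain(img):
    sm = ot.smooth_3x3(img)
    thr = ot.solve_thresholds(ot.histogram(sm))
    binary = ot.binarize(sm, thr.t1, "below")
    oe = ml.element_from_threshold(thr.t1, 0.3)
    ce = ml.element_from_threshold(thr.t1, 0.7)
    cleaned = ml.open_close(binary, oe.size, ce.size)
    rough = ml.rough_pupil(*ml.project(cleaned))
    return thr, rough


class TestCollectBoundary:
    def test_clean_ellipse_points_on_contour(self):
        from pupilglint import synthetic_eye as se
        pupil = se.PupilTruth(center=(320.0, 240.0), a=55, b=45, tilt_deg=30,
                              gray=20)
        truth = se.SceneTruth(
            pupil=pupil,
            iris=se.IrisTruth(center=(320.0, 240.0), radius=130, gray=120),
            background_gray=200, glints=(), noise_sigma=2.0, blur_sigma=1.0,
            seed=3)
        img = se.render(truth)
        thr, rough = _pupil_chain(img)
        pts = collect_boundary(img, rough, thr, CrrlParams())
        assert len(pts) >= 30
        for p in pts:
            assert abs(pupil.signed_distance(p.x, p.y)) <= 1.0

    def test_contour_glint_survivors_on_contour(self):
        from pupilglint import synthetic_eye as se
        truth = se.sample_scene(4, "contour_glint")
        img = se.render(truth)
        thr, rough = _pupil_chain(img)
        pts = collect_boundary(img, rough, thr, CrrlParams())
        assert len(pts) >= 6
        for p in pts:
            assert abs(truth.pupil.signed_distance(p.x, p.y)) <= 1.0

    def test_points_within_annulus(self, clean_scene):
        truth, img = clean_scene
        thr, rough = _pupil_chain(img)
        params = CrrlParams()
        pts = collect_boundary(img, rough, thr, params)
        cx, cy = rough.center_rough
        rp = rough.radius_rough
        for p in pts:
            d = math.hypot(p.x - cx, p.y - cy)
            assert 0.5 * rp - params.sample_step <= d <= 1.5 * rp + params.sample_step

    def test_no_point_in_glint_footprint(self):
        from pupilglint import synthetic_eye as se
        for seed in (0, 1, 2):
            truth = se.sample_scene(seed, "contour_glint")
            img = se.render(truth)
            thr, rough = _pupil_chain(img)
            pts = collect_boundary(img, rough, thr, CrrlParams())
            for p in pts:
                for g in truth.glints:
                    assert math.hypot(p.x - g.center[0], p.y - g.center[1]) \
                        >= 2 * max(g.sigma_x, g.sigma_y)

    def test_blank_image_fails(self):
        img = GrayImage(np.zeros((100, 100), dtype=np.uint8))
        rough = RoughPupil(l1=30, l2=40, l3=30, l4=40)
        counts = np.zeros(256, dtype=np.int64)
        counts[0] = 10000
        thr = ot.solve_thresholds(ot.GrayHistogram(counts))
        with pytest.raises(DetectionError):
            collect_boundary(img, rough, thr, CrrlParams())


class TestRotationEquivariance:
    def test_rotated_scene(self):
        """90-degree rotation: the fitted center is equivariant within
        0.2 px and rotated boundary points stay on the rotated contour.

        Exact 0.2-px point correspondence is impossible: the rough-center
        convention op' = l1 + l2/2 carries a half-pixel offset that flips
        sign under the reflection inside a 90-degree rotation, shifting ray
        origins by 1 px between orientations."""
        from pupilglint import pipeline, synthetic_eye as se
        truth = se.sample_scene(11, "clean")
        img = se.render(truth)
        w = img.pixels.shape[1]
        r1 = pipeline.detect(img)
        r2 = pipeline.detect(GrayImage(np.rot90(img.pixels, 1).copy()))
        assert r1.failure is None and r2.failure is None
        (x1, y1), (x2, y2) = r1.pupil_center, r2.pupil_center
        assert math.hypot(x2 - y1, y2 - (w - 1 - x1)) <= 0.2
        pts1 = r1.diagnostics["boundary_points"]
        pts2 = r2.diagnostics["boundary_points"]
        assert abs(len(pts1) - len(pts2)) <= 2
        for bx, by in pts2:
            ox, oy = w - 1 - by, bx  # map back to the original frame
            assert abs(truth.pupil.signed_distance(ox, oy)) <= 0.5
        # point sets correspond within the 1-px ray-origin shift + tolerance
        for x, y in pts1:
            mapped = (y, w - 1 - x)
            d = min(math.hypot(mapped[0] - qx, mapped[1] - qy)
                    for qx, qy in pts2)
            assert d <= 1.2
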