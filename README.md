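# pupilglint

Pupil and glint (corneal-reflection) center detection for near-infrared eye
images, as used by PCCR-style gaze trackers, plus a seeded synthetic eye
renderer with exact ground truth for end-to-end evaluation.

The detector composes five stages:

1. **Three-class Otsu thresholding** (`trimodal_otsu`) — after 3×3 mean
   smoothing, the threshold pair (T1, T2) maximizing the between-class
   variance criterion is found by exhaustive search over T1 ∈ [1, 50],
   T2 ∈ [T1+1, 150] (prefix-sum moments make each candidate O(1); near-ties
   are resolved in exact integer arithmetic). T1 binarizes the pupil.
2. **Morphology + projections** (`morph_locate`) — opening (≈0.3·T1 square
   element) removes eyelash remnants, closing (≈0.7·T1) fills glint holes;
   the longest positive runs of the column/row foreground projections give
   the rough pupil box, center op′ = (l1 + l2/2, l3 + l4/2) and radius
   rp′ = (l2 + l4)/4.
3. **Circular ring rays location** (`crrl`) — 36 rays (10° apart) cross the
   annulus [0.5·rp′, 1.5·rp′]; Sobel gradient amplitude is sampled
   bilinearly along each ray, supra-threshold samples cluster, rays with
   anything other than one clean cluster are interference (glints,
   reflections, lashes) and are discarded, and surviving peaks are refined
   to subpixel by a cubic-spline argmax. Thresholds scale with
   δ = T2 − T1.
4. **Constrained TLS ellipse fit** (`tls_ellipse`) — the conic
   Ax² + Bxy + Cy² + Dx + Ey + F = 0 under A + C = 1, solved as a centered
   total-least-squares system τ′ = (XᵀX − γ²min·I)⁻¹XᵀZ with γmin from a
   self-contained cyclic Jacobi eigen solver on LᵀL, L = [−Z, X]. The pupil
   center follows from the conic coefficients.
5. **Gaussian glint fitting** (`glint`) — binarize at 240, clean with a 2×2
   element, label 8-connected regions, and fit each region's log-intensity
   with the linear model z = ax² + by² + cx + dy + e via the same TLS
   solver; the center is (−c/2a, −d/2b).

`synthetic_eye` renders eye-like scenes (dark elliptical pupil, iris disk,
bright skin, 2×2 near-saturated Gaussian glint grid, eyelash strokes, blur,
sensor noise) deterministically per seed, and `evaluate` scores detections
against the ground truth (stability % and RMS center error).

## Coordinate convention

`x` is the column index, `y` the row index, both 0-based, pixel centers at
integer coordinates. All reported centers (pupil and glints) use this
convention.

## CLI

```sh
# single image: JSON to stdout, optional overlay/JSON outputs
pupilglint detect --image eye.png [--config cfg.yaml] [--overlay out.png] [--json out.json]

# batch: one CSV row per image (pupil x,y then up to 4 glint centers, 2 decimals)
pupilglint batch --glob 'dir/*.png' --out results.csv

# synthetic data: PNGs + per-image ground-truth JSON
pupilglint synth --n 100 --difficulty contour_glint --seed 42 --out scenes/

# evaluation against rendered ground truth
pupilglint eval --images scenes/ --truth scenes/ --report report.json
```

`--config` accepts a YAML file overriding any default in
`pupilglint.config.DEFAULTS` (e.g. `glint.threshold`, `crrl.n_rays`,
`otsu.t1_range`).

### Result JSON schema

```json
{
  "pupil_center": [x, y] | null,
  "pupil_ellipse": {"A":, "B":, "C":, "D":, "E":, "F":} | null,
  "glints": [{"id":, "center": [x, y], "sigma": [sx, sy], "amplitude":}, ...],
  "failure": null | "<stage name>",
  "diagnostics": {"thresholds": {...}, "rough": {...}, "n_boundary_points":, ...}
}
```

The CSV schema is flat: `image, pupil_x, pupil_y, glint1_x, glint1_y, ...,
glint4_x, glint4_y` with `NA` markers for missing values.

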