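"""Stability and RMS-error scoring of detection results against ground truth.

A pupil detection counts as successful when the pipeline completed and the
fitted center lies within ``success_radius`` (default 5 px) of the true
center; stability is the percentage of successes and the RMS error is
computed over successes only.  Detected glints are matched to true glints
by nearest neighbor within ``glint_match_radius`` (default 3 px); unmatched
true glints count as failures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import DetectionResult
from .synthetic_eye import SceneTruth

__all__ = ["EvalReport", "score"]


@dataclass
class EvalReport:
    n_images: int
    pupil_stability: float      # percent
    pupil_rms_error: float      # px, over successful detections
    glint_stability: float      # percent of true glints matched
    glint_rms_error: float      # px, over matched glints
    records: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "pupil_stability": self.pupil_stability,
            "pupil_rms_error": self.pupil_rms_error,
            "glint_stability": self.glint_stability,
            "glint_rms_error": self.glint_rms_error,
            "records": self.records,
        }


def _match_glints(detected, truths, radius: float):
    """Greedy nearest-neighbor matching; returns per-truth match errors."""
    det = [(g.center[0], g.center[1]) for g in detected]
    errors = []
    used = set()
    for t in truths:
        best, best_d = None, radius
        for j, (dx, dy) in enumerate(det):
            if j in used:
                continue
            dist = math.hypot(dx - t.center[0], dy - t.center[1])
            if dist <= best_d:
                best, best_d = j, dist
        if best is not None:
            used.add(best)
            errors.append(best_d)
        else:
            errors.append(None)
    return errors


def score(results, truths, success_radius: float = 5.0,
          glint_match_radius: float = 3.0) -> EvalReport:
    if len(results) != len(truths):
        raise ValueError(f"length mismatch: {len(results)} results, "
                         f"{len(truths)} truths")
    records = []
    pupil_sq = []
    n_pupil_ok = 0
    glint_sq = []
    n_glints_true = 0
    n_glints_ok = 0

    for res, truth in zip(results, truths):
        rec = {"failure": res.failure}
        if res.pupil_center is not None and res.failure is None:
            tx, ty = truth.pupil.center
            err = math.hypot(res.pupil_center[0] - tx, res.pupil_center[1] - ty)
            rec["pupil_error"] = err
            if err <= success_radius:
                n_pupil_ok += 1
                pupil_sq.append(err * err)
            else:
                rec["gross_error"] = True
        glint_errs = _match_glints(res.glints, truth.glints, glint_match_radius)
        rec["glint_errors"] = glint_errs
        n_glints_true += len(truth.glints)
        for e in glint_errs:
            if e is not None:
                n_glints_ok += 1
                glint_sq.append(e * e)
        records.append(rec)

    n = len(results)
    report = EvalReport(
        n_images=n,
        pupil_stability=100.0 * n_pupil_ok / n if n else 0.0,
        pupil_rms_error=math.sqrt(np.mean(pupil_sq)) if pupil_sq else 0.0,
        glint_stability=(100.0 * n_glints_ok / n_glints_true
                         if n_glints_true else 0.0),
        glint_rms_error=math.sqrt(np.mean(glint_sq)) if glint_sq else 0.0,
        records=records,
    )
    return report
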