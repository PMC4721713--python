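"""Three-class optimal threshold selection (improved Otsu).

Gray levels are split into three groups ``{0..T1}``, ``{T1+1..T2}`` and
``{T2+1..255}``; the pair ``(T1, T2)`` maximizing the between-class
criterion

    g(T1, T2) = w0*(h0-h)^2 + w1*(h1-h)^2 + w2*(h2-h)^2

is found by exhaustive search over a constrained grid (``T1`` in [1, 50],
``T2`` in [T1+1, 150] by default).  Class moments come from prefix sums of
``p_i``, ``i*p_i`` and ``i^2*p_i``, so each candidate pair is O(1).  The
stationarity residuals ``|2*T1 - h0 - h1|`` and ``|2*T2 - h1 - h2|`` are
reported as diagnostics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import ndimage

from .core_io import BinaryImage, GrayImage

__all__ = [
    "GrayHistogram",
    "ThresholdPair",
    "smooth_3x3",
    "histogram",
    "class_stats",
    "solve_thresholds",
    "binarize",
]

N_LEVELS = 256


@dataclass(frozen=True)
class GrayHistogram:
    """Integer counts per gray level 0..255 with derived probabilities."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (N_LEVELS,):
            raise ValueError(f"histogram must have {N_LEVELS} bins, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("negative histogram count")
        if c.sum() <= 0:
            raise ValueError("empty histogram")
        object.__setattr__(self, "counts", c.astype(np.int64, copy=False))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @cached_property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.total

    # prefix sums over levels 0..k of p, i*p, i^2*p (index k inclusive)
    @cached_property
    def _prefix(self) -> tuple:
        p = self.probabilities
        i = np.arange(N_LEVELS, dtype=np.float64)
        return np.cumsum(p), np.cumsum(i * p), np.cumsum(i * i * p)

    @property
    def mean(self) -> float:
        return float(self._prefix[1][-1])

    @property
    def variance(self) -> float:
        cp, cip, ci2p = self._prefix
        return float(ci2p[-1] - cip[-1] ** 2)


@dataclass(frozen=True)
class ThresholdPair:
    """Optimal (T1, T2) with the class statistics at the optimum."""

    t1: int
    t2: int
    omega: tuple
    h: tuple          # (h0, h1, h2)
    h_global: float
    sigma2: tuple     # (s0^2, s1^2, s2^2)
    sigma_w2: float
    criterion_g: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.t1 < self.t2 < 255):
            raise ValueError(f"need 0 < T1 < T2 < 255, got ({self.t1}, {self.t2})")

    @property
    def delta(self) -> float:
        """delta = T2 - T1; scales the gradient-amplitude threshold."""
        return float(self.t2 - self.t1)


def smooth_3x3(image: GrayImage) -> GrayImage:
    """Replace each pixel by its 3x3 neighborhood mean (edge replication)."""
    f = image.as_float()
    sums = ndimage.correlate(f, np.ones((3, 3)), mode="nearest")
    out = np.floor(sums / 9.0 + 0.5)
    return GrayImage(out.astype(np.uint8))


def histogram(image: GrayImage) -> GrayHistogram:
    px = np.asarray(image.pixels)
    if not np.issubdtype(px.dtype, np.integer):
        px = np.floor(px + 0.5).astype(np.int64)
    counts = np.bincount(px.ravel(), minlength=N_LEVELS)
    return GrayHistogram(counts)


def _segment_moments(prefix, lo: int, hi: int):
    """(omega, mean, variance, empty?) of levels lo..hi inclusive."""
    cp, cip, ci2p = prefix
    p0 = cp[hi] - (cp[lo - 1] if lo > 0 else 0.0)
    p1 = cip[hi] - (cip[lo - 1] if lo > 0 else 0.0)
    p2 = ci2p[hi] - (ci2p[lo - 1] if lo > 0 else 0.0)
    if p0 <= 0.0:
        # empty class: mean at the range midpoint, zero variance
        return 0.0, (lo + hi) / 2.0, 0.0, True
    mean = p1 / p0
    var = max(p2 / p0 - mean * mean, 0.0)
    return float(p0), float(mean), float(var), False


def class_stats(hist: GrayHistogram, t1: int, t2: int):
    """Class probabilities, means, variances, sigma_W^2 and criterion g.

    Returns ``(omega, h, sigma2, sigma_w2, criterion_g, diagnostics)``.
    """
    if not (0 < t1 < t2 < 255):
        raise ValueError(f"need 0 < T1 < T2 < 255, got ({t1}, {t2})")
    prefix = hist._prefix
    segs = [
        _segment_moments(prefix, 0, t1),
        _segment_moments(prefix, t1 + 1, t2),
        _segment_moments(prefix, t2 + 1, 255),
    ]
    omega = tuple(s[0] for s in segs)
    h = tuple(s[1] for s in segs)
    sigma2 = tuple(s[2] for s in segs)
    empty = [k for k, s in enumerate(segs) if s[3]]
    h_glob = hist.mean
    sigma_w2 = sum(w * v for w, v in zip(omega, sigma2))
    g = sum(w * (m - h_glob) ** 2 for w, m in zip(omega, h))
    diagnostics = {
        "empty_classes": empty,
        "eq6_residuals": (abs(2 * t1 - h[0] - h[1]), abs(2 * t2 - h[1] - h[2])),
    }
    return omega, h, sigma2, float(sigma_w2), float(g), diagnostics


def _exact_criterion(cw: np.ndarray, cm: np.ndarray, t1: int, t2: int):
    """Between-class criterion as an exact rational (up to a positive factor).

    With integer class counts W_k and first moments M_k, the criterion
    g = Σ ω_k (h_k − h)² equals Σ (N·M_k − W_k·M)² / W_k up to the positive
    constant 1/N³, so exact integer arithmetic gives a total order on
    candidate pairs that float rounding cannot scramble.
    """
    from fractions import Fraction

    n_tot = int(cw[-1])
    m_tot = int(cm[-1])
    bounds = ((0, t1), (t1 + 1, t2), (t2 + 1, 255))
    q = Fraction(0)
    for lo, hi in bounds:
        w = int(cw[hi]) - (int(cw[lo - 1]) if lo > 0 else 0)
        m = int(cm[hi]) - (int(cm[lo - 1]) if lo > 0 else 0)
        if w > 0:
            q += Fraction((n_tot * m - w * m_tot) ** 2, w)
    return q


def solve_thresholds(hist: GrayHistogram, t1_range=(1, 50), t2_max: int = 150
                     ) -> ThresholdPair:
    """Exhaustive argmax of the between-class criterion over the grid.

    A vectorized float pass narrows the grid to near-maximal candidates;
    the winner among them is decided in exact integer arithmetic (counts
    are integers), so the result is the true argmax independent of
    floating-point rounding on plateaus.  Ties break to the smallest T1,
    then the smallest T2.  Histograms with fewer than three occupied modes
    still return the grid maximizer, flagged "degenerate" if any class is
    empty at the optimum.
    """
    t1_lo, t1_hi = int(t1_range[0]), int(t1_range[1])
    if not (1 <= t1_lo <= t1_hi < t2_max <= 254):
        raise ValueError(f"bad search bounds: t1_range={t1_range}, t2_max={t2_max}")
    cp, cip, _ = hist._prefix
    h_glob = hist.mean

    t1s = np.arange(t1_lo, t1_hi + 1)
    t2s = np.arange(t1_lo + 1, t2_max + 1)
    T1, T2 = np.meshgrid(t1s, t2s, indexing="ij")
    valid = T2 > T1

    w0 = cp[T1]
    m0 = cip[T1]
    w1 = cp[T2] - cp[T1]
    m1 = cip[T2] - cip[T1]
    w2 = 1.0 - cp[T2]
    m2 = cip[-1] - cip[T2]

    # w*(h_k - h)^2 = (m_k - w_k*h)^2 / w_k, with empty classes contributing 0
    def _term(w, m):
        num = (m - w * h_glob) ** 2
        return np.divide(num, w, out=np.zeros_like(num), where=w > 0)

    g = _term(w0, m0) + _term(w1, m1) + _term(w2, m2)
    g[~valid] = -np.inf

    gmax = float(np.max(g))
    margin = 1e-9 * max(abs(gmax), 1e-300)
    cand_i, cand_j = np.nonzero(g >= gmax - margin)

    # exact integer prefix sums for the rational tie-break pass
    counts = hist.counts
    cw = np.cumsum(counts)
    cm = np.cumsum(np.arange(N_LEVELS, dtype=np.int64) * counts)
    best_q = None
    t1 = t2 = None
    order = np.lexsort((t2s[cand_j], t1s[cand_i]))  # smallest T1, then T2
    for k in order:
        c1, c2 = int(t1s[cand_i[k]]), int(t2s[cand_j[k]])
        q = _exact_criterion(cw, cm, c1, c2)
        if best_q is None or q > best_q:
            best_q, t1, t2 = q, c1, c2

    omega, h, sigma2, sigma_w2, criterion_g, diagnostics = class_stats(hist, t1, t2)
    diagnostics["degenerate"] = bool(diagnostics["empty_classes"])
    diagnostics["search"] = {"t1_range": [t1_lo, t1_hi], "t2_max": t2_max}
    return ThresholdPair(
        t1=t1, t2=t2, omega=omega, h=h, h_global=h_glob, sigma2=sigma2,
        sigma_w2=sigma_w2, criterion_g=criterion_g, diagnostics=diagnostics,
    )


def binarize(image: GrayImage, t: int, foreground: str = "below") -> BinaryImage:
    """Threshold: ``below`` → pixel <= T is 1 (pupil); ``above`` → pixel >= T is 1."""
    if not (0 <= t <= 255):
        raise ValueError(f"threshold out of range: {t}")
    px = image.pixels
    if foreground == "below":
        mask = px <= t
        meaning = f"intensity <= {t}"
    elif foreground == "above":
        mask = px >= t
        meaning = f"intensity >= {t}"
    else:
        raise ValueError(f"foreground must be 'below' or 'above', got {foreground!r}")
    return BinaryImage(mask.astype(np.uint8), foreground_meaning=meaning)
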