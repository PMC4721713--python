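"""Independent brute-force oracles used by unit and acceptance tests."""

from fractions import Fraction

import numpy as np


def brute_force_thresholds(hist, t1_range=(1, 50), t2_max=150):
    """Exhaustive argmax of the between-class criterion by direct summation.

    Independent of the package's prefix-sum/vectorized path: class weights
    and means come from plain slice sums, a float pass ranks candidates and
    near-maximal ones are compared in exact rational arithmetic (histogram
    counts are integers), with smallest-T1-then-T2 tie-breaking.  This makes
    "equals the brute-force argmax exactly" well defined on plateaus.
    """
    counts = np.asarray(hist.counts, dtype=np.int64)
    n_tot = int(counts.sum())
    i = np.arange(256, dtype=np.int64)
    m_tot = int((i * counts).sum())
    p = counts / n_tot
    mean = m_tot / n_tot

    scored = []
    for t1 in range(t1_range[0], t1_range[1] + 1):
        for t2 in range(t1 + 1, t2_max + 1):
            g = 0.0
            for lo, hi in ((0, t1), (t1 + 1, t2), (t2 + 1, 255)):
                w = p[lo:hi + 1].sum()
                if w > 0:
                    m = (i[lo:hi + 1] * p[lo:hi + 1]).sum() / w
                    g += w * (m - mean) ** 2
            scored.append((g, t1, t2))
    gmax = max(g for g, *_ in scored)
    margin = 1e-9 * max(abs(gmax), 1e-300)

    best_q, best = None, None
    for g, t1, t2 in scored:  # already in (T1, T2) ascending order
        if g < gmax - margin:
            continue
        q = Fraction(0)
        for lo, hi in ((0, t1), (t1 + 1, t2), (t2 + 1, 255)):
            w = int(counts[lo:hi + 1].sum())
            m = int((i[lo:hi + 1] * counts[lo:hi + 1]).sum())
            if w > 0:
                q += Fraction((n_tot * m - w * m_tot) ** 2, w)
        if best_q is None or q > best_q:
            best_q, best = q, (t1, t2)
    return best
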