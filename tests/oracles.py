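"""Brute-force reference implementations used only for cross-checking.

These deliberately re-state the rules in the most literal way possible
(quadratic pair scans, explicit step-up loops) and share no code with the
package implementations they check.
"""

from __future__ import annotations

import numpy as np


def oracle_filter(peaks: list[tuple[int, int]], min_count: int = 6, min_frac: float = 0.05):
    """peaks: (site, count) tuples; keep count > 5 and >= 5% of the total."""
    total = sum(c for _, c in peaks)
    return [(s, c) for (s, c) in peaks if c >= min_count and c >= min_frac * total]


def oracle_merge(peaks: list[tuple[int, int]], strand: str = "+", min_dist: int = 50):
    """Iterative closest-pair merging by literal pair enumeration.

    Scans every unordered pair, merges the closest one (< min_dist; ties
    at the lower coordinate), placing the result at the stronger member's
    site (count ties -> the more 3' position) with summed counts.
    """
    peaks = sorted(peaks)
    while True:
        best = None  # (dist, lower_site, i, j)
        for i in range(len(peaks)):
            for j in range(len(peaks)):
                if i == j:
                    continue
                d = abs(peaks[i][0] - peaks[j][0])
                lo = min(peaks[i][0], peaks[j][0])
                key = (d, lo)
                if d < min_dist and (best is None or key < best[:2]):
                    best = (d, lo, min(i, j), max(i, j))
        if best is None:
            return peaks
        _, _, i, j = best
        (s1, c1), (s2, c2) = peaks[i], peaks[j]
        if c1 > c2:
            site = s1
        elif c2 > c1:
            site = s2
        else:
            site = max(s1, s2) if strand == "+" else min(s1, s2)
        peaks = [p for k, p in enumerate(peaks) if k not in (i, j)]
        peaks.append((site, c1 + c2))
        peaks.sort()


def oracle_bh(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


def oracle_hypergeom_tail(k: int, n_u: int, n_a: int, n_b: int) -> float:
    """P(overlap >= k) by explicit summation of hypergeometric terms."""
    from math import comb

    total = 0
    for x in range(k, min(n_a, n_b) + 1):
        total += comb(n_a, x) * comb(n_u - n_a, n_b - x)
    return total / comb(n_u, n_b)
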