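"""Independent brute-force oracles used only by the test suite.

These are deliberately naive re-implementations — BFS labeling, exhaustive
rank-sum enumeration, per-pixel scoring — kept free of any code path they
check.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb

import numpy as np


def bfs_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components of a boolean mask by breadth-first search."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = set()
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                while q:
                    r, c = q.popleft()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < rows and 0 <= cc < cols and \
                                    mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                q.append((rr, cc))
                comps.append(comp)
    return comps


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by exhaustive enumeration (no ties).

    U is counted for sample ``a``; the p-value enumerates all C(n, n_a)
    assignments of the pooled ranks.
    """
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n_a, n = len(a), len(a) + len(b)

    def u_of(idx_set):
        vals = [pooled[i] for i in idx_set]
        rest = [pooled[i] for i in range(n) if i not in idx_set]
        return sum(1 for x in vals for y in rest if x > y)

    u_obs = sum(1 for x in a for y in b if x > y)
    total = comb(n, n_a)
    u_all = [u_of(set(ix)) for ix in combinations(range(n), n_a)]
    mean_u = n_a * (n - n_a) / 2.0
    dev = abs(u_obs - mean_u)
    count = sum(1 for u in u_all if abs(u - mean_u) >= dev - 1e-12)
    return float(u_obs), count / total


def hb_score_pixels(hb: np.ndarray, region: np.ndarray, threshold: float,
                    min_area_px: int, bg_median: float,
                    exclude: np.ndarray | None = None,
                    vessel_mask: np.ndarray | None = None,
                    proximity_px: float | None = None) -> float:
    """Per-pixel integrated-intensity oracle for the hemoglobin scores.

    Thresholds within the region, groups pixels with BFS, applies the area
    filter and (optionally) the minimum-distance-to-vessel condition, and
    sums background-subtracted intensities.
    """
    mask = region & (hb > threshold)
    if exclude is not None:
        mask = mask & ~exclude
    total = 0.0
    vessel_px = list(zip(*np.nonzero(vessel_mask))) if vessel_mask is not None else []
    for comp in bfs_components(mask):
        if len(comp) < min_area_px:
            continue
        if proximity_px is not None:
            dmin = min((np.hypot(r - vr, c - vc)
                        for (r, c) in comp for (vr, vc) in vessel_px),
                       default=np.inf)
            if dmin > proximity_px:
                continue
        total += sum(hb[r, c] - bg_median for r, c in comp)
    return total


def grubbs_reference(values, alpha):
    """Direct-formula Grubbs evaluation (statistic, critical value, index)."""
    from scipy import stats as sps
    x = np.asarray(values, dtype=float)
    n = x.size
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / x.std(ddof=1)
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    crit = (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))
    return g, crit, idx
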