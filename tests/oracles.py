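"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plainly as possible — explicit loops and
if/else chains — deliberately not sharing code paths with the
implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def morans_i(field: np.ndarray) -> float:
    """Moran's I under rook adjacency, computed by a direct double loop."""
    n_lat, n_lon = field.shape
    flat = field.ravel()
    n = flat.size
    mean = flat.mean()
    dev = flat - mean

    num = 0.0
    w_sum = 0.0
    for i in range(n_lat):
        for j in range(n_lon):
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < n_lat and 0 <= nj < n_lon:
                    num += dev[i * n_lon + j] * dev[ni * n_lon + nj]
                    w_sum += 1.0
    denom = (dev**2).sum()
    return (n / w_sum) * (num / denom)


def percentile_linear(pool, p: float) -> float:
    """Sort-and-interpolate percentile (linear / "type 7") from scratch."""
    xs = sorted(float(v) for v in pool)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (p / 100.0) * (n - 1)
    lo = math.floor(h)
    hi = math.ceil(h)
    if lo == hi:
        return xs[int(h)]
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def min_rule_suitability(memberships_per_cell):
    """Loop-over-parameters minimum for one cell's membership scores."""
    best = 1.0
    for m in memberships_per_cell:
        if math.isnan(m):
            return float("nan")
        if m < best:
            best = m
    return best


def trapezoid(x: float, x1: float, x2: float, x3: float, x4: float) -> float:
    """Scalar trapezoid membership, written as an explicit if/else chain."""
    if math.isnan(x):
        return float("nan")
    if x < x1 or x > x4:
        return 0.0
    if x2 <= x <= x3:
        return 1.0
    if x < x2:
        return (x - x1) / (x2 - x1)
    return (x4 - x) / (x4 - x3)


def classify_cell(
    lst: float, lsf: float, fraction: float, factor: float, threshold: float
) -> str:
    """One cell of the transition rule table, as a literal if/else chain."""
    if math.isnan(lst) or math.isnan(lsf) or math.isnan(fraction):
        return "missing"
    used = fraction >= 0.01
    if used:
        if lsf > factor * lst:
            return "unaltered_used"
        return "abandoned"
    if lsf > threshold:
        return "added"
    return "unaltered_notused"


def classify_grid(lst, lsf, fraction, factor: float, percentile: float):
    """Full oracle for the rule engine: pool, threshold, then per-cell rules."""
    pool = []
    n_lat, n_lon = lst.shape
    for i in range(n_lat):
        for j in range(n_lon):
            if math.isnan(fraction[i, j]) or math.isnan(lst[i, j]):
                continue
            if fraction[i, j] >= 0.01:
                pool.append(lst[i, j])
    threshold = percentile_linear(pool, percentile)
    out = np.empty((n_lat, n_lon), dtype=object)
    for i in range(n_lat):
        for j in range(n_lon):
            out[i, j] = classify_cell(
                lst[i, j], lsf[i, j], fraction[i, j], factor, threshold
            )
    return out, threshold


def accumulate_areas(codes, lat_centers, d_lat: float, d_lon: float, radius: float):
    """Cell-by-cell km² accumulation per category code."""
    totals: dict[int, float] = {}
    n_lat, n_lon = codes.shape
    for i in range(n_lat):
        top = math.radians(lat_centers[i] + d_lat / 2.0)
        bot = math.radians(lat_centers[i] - d_lat / 2.0)
        area = radius**2 * math.radians(d_lon) * (math.sin(top) - math.sin(bot))
        for j in range(n_lon):
            code = int(codes[i, j])
            totals[code] = totals.get(code, 0.0) + area
    return totals
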