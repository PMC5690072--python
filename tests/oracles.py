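"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (O(n^2) scans, explicit normal
equations, sort-based percentiles) and shares no code with the package's own
algorithms beyond numpy primitives.
"""

from __future__ import annotations

import numpy as np


def moving_average_edge_padded(y: np.ndarray, win: int) -> np.ndarray:
    """Centred boxcar with edge-value padding (independent of scipy)."""
    if win == 1:
        return np.asarray(y, dtype=float)
    h = win // 2
    padded = np.concatenate([np.full(h, y[0]), y, np.full(h, y[-1])])
    kernel = np.ones(win) / win
    return np.convolve(padded, kernel, mode="valid")


def local_extrema(y: np.ndarray, kind: str) -> np.ndarray:
    """Exhaustive scan for local maxima/minima with plateau-midpoint handling."""
    s = np.asarray(y, dtype=float) if kind == "max" else -np.asarray(y, dtype=float)
    out = []
    i = 1
    n = len(s)
    while i < n - 1:
        if s[i] > s[i - 1]:
            j = i
            while j < n - 1 and s[j + 1] == s[j]:
                j += 1
            if j < n - 1 and s[j + 1] < s[j]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.array(out, dtype=int)


def prominence(y: np.ndarray, i: int) -> float:
    """Topographic prominence of the peak at index i (peak = local max of y)."""
    s = np.asarray(y, dtype=float)
    left_min = s[i]
    j = i - 1
    while j >= 0 and s[j] <= s[i]:
        left_min = min(left_min, s[j])
        j -= 1
    right_min = s[i]
    j = i + 1
    while j < len(s) and s[j] <= s[i]:
        right_min = min(right_min, s[j])
        j += 1
    return float(s[i] - max(left_min, right_min))


def distance_filter(idx: np.ndarray, heights: np.ndarray, distance: int) -> np.ndarray:
    """Greedy highest-first thinning: drop peaks within ``distance`` of a keeper."""
    order = np.argsort(heights, kind="stable")[::-1]
    keep = np.ones(len(idx), dtype=bool)
    for oi in order:
        if not keep[oi]:
            continue
        for oj in range(len(idx)):
            if oj != oi and keep[oj] and abs(int(idx[oj]) - int(idx[oi])) < distance:
                if heights[oj] < heights[oi] or (heights[oj] == heights[oi] and oj < oi):
                    keep[oj] = False
    return idx[keep]


def detect_peaks_oracle(
    t: np.ndarray,
    y: np.ndarray,
    period_s: float,
    min_sep_frac: float = 0.4,
    prominence_frac: float = 0.2,
    smooth_win: int = 5,
):
    """Brute-force twin of the package's peak detector.

    Returns (max_indices, min_indices) into the input arrays.
    """
    ys = moving_average_edge_padded(np.asarray(y, dtype=float), smooth_win)
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(min_sep_frac * period_s / dt)))

    imax = local_extrema(ys, "max")
    imin = local_extrema(ys, "min")
    imax = distance_filter(imax, ys[imax], distance) if len(imax) else imax
    imin = distance_filter(imin, -ys[imin], distance) if len(imin) else imin
    if len(imax) == 0 and len(imin) == 0:
        return imax, imin

    amplitude = float(np.percentile(ys, 97.5) - np.percentile(ys, 2.5))
    thr = prominence_frac * max(amplitude, 0.0)
    if thr > 0:
        imax = np.array([i for i in imax if prominence(ys, i) >= thr], dtype=int)
        imin = np.array([i for i in imin if prominence(-ys, i) >= thr], dtype=int)
    return imax, imin


def normal_equations_fit(x: np.ndarray, v: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Explicit 5x5 normal-equations solve for the quadratic model."""
    A = np.column_stack([x * x, x, np.ones_like(x), v * v, v])
    return np.linalg.solve(A.T @ A, A.T @ y)


def percentile_sorted(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile computed from first principles."""
    s = np.sort(np.asarray(values, dtype=float))
    h = (len(s) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return float(s[lo] + (h - lo) * (s[hi] - s[lo]))
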