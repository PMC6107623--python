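"""Independent brute-force oracles used by the test suite.

These deliberately re-derive, by exhaustive scan, what the library computes
with vectorised/scipy primitives, so the two routes can be compared on small
inputs.
"""

from __future__ import annotations

import numpy as np


def brute_local_maxima(x: np.ndarray) -> list[int]:
    """Indices of strict interior local maxima (boundary samples excluded)."""
    return [
        i
        for i in range(1, len(x) - 1)
        if x[i - 1] < x[i] and x[i] > x[i + 1]
    ]


def brute_prominence(x: np.ndarray, i: int) -> float:
    """Topographic prominence: peak height above the higher of the two bases,
    each base being the minimum between the peak and the next higher sample
    (or the signal border) on that side."""
    left_min = x[i]
    j = i - 1
    while j >= 0 and x[j] <= x[i]:
        left_min = min(left_min, x[j])
        j -= 1
    right_min = x[i]
    j = i + 1
    while j < len(x) and x[j] <= x[i]:
        right_min = min(right_min, x[j])
        j += 1
    return x[i] - max(left_min, right_min)


def brute_select_by_distance(
    peaks: list[int], heights: np.ndarray, distance: int
) -> list[int]:
    """Greedy distance pruning: highest peak first, suppress all unkept peaks
    closer than ``distance`` samples."""
    keep = [True] * len(peaks)
    order = list(np.argsort(heights, kind="stable"))[::-1]
    for oi in order:
        if not keep[oi]:
            continue
        for j in range(len(peaks)):
            if j != oi and keep[j] and abs(peaks[j] - peaks[oi]) < distance:
                keep[j] = False
    return [p for p, k in zip(peaks, keep) if k]


def brute_detect_peaks(
    x: np.ndarray, prominence: float, distance: int = 1
) -> tuple[list[int], list[int]]:
    """Full exhaustive peak/trough scan with the same prominence/distance
    rules as the library's detector: local maxima, distance pruning by
    height, prominence filter, then the minimum between consecutive
    surviving peaks as troughs."""
    x = np.asarray(x, dtype=float)
    cand = brute_local_maxima(x)
    if distance > 1:
        cand = sorted(brute_select_by_distance(cand, x[cand], distance))
    peaks = [i for i in cand if brute_prominence(x, i) >= prominence]
    troughs = []
    for a, b in zip(peaks, peaks[1:]):
        seg = list(x[a : b + 1])
        troughs.append(a + seg.index(min(seg)))
    return peaks, troughs


def brute_autocorr_period(x: np.ndarray, dt: float) -> float | None:
    """First local maximum of the (brute force, O(n^2)) autocorrelation."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    n = len(x)
    denom = float(np.dot(x, x))
    if denom <= 0:
        return None
    ac = [sum(x[i] * x[i + lag] for i in range(n - lag)) / denom for lag in range(n)]
    for lag in range(2, n - 1):
        if ac[lag - 1] < ac[lag] > ac[lag + 1] and ac[lag] > 0.05:
            return lag * dt
    return None
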