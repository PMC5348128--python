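"""Penalized least-squares changepoint segmentation of 1D traces.

Optimal partitioning by dynamic programming with an L2 (piecewise-constant
mean) cost and a BIC-style penalty per changepoint.  Deterministic given
the trace; O(n²) with cumulative sums, adequate for scan-line traces of a
few thousand points.
"""

from __future__ import annotations

import numpy as np


def _mad_sigma(y: np.ndarray) -> float:
    """Robust noise scale from the median absolute first difference."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0))


def segment_mean_shift(y, penalty: float | None = None, min_size: int = 5) -> list[int]:
    """Changepoint indices of a piecewise-constant signal.

    Minimizes sum of within-segment squared residuals + penalty per
    breakpoint.  ``penalty`` defaults to ``2·σ²·ln(n)`` with σ estimated
    robustly from first differences (the classical 2σ²·ln n model-selection
    penalty; larger factors merge near-threshold single-fluorophore steps).
    Returned indices are segment start positions (excluding 0), sorted
    ascending.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2 * min_size:
        return []
    if penalty is None:
        sigma = _mad_sigma(y)
        if sigma == 0.0:
            sigma = max(float(np.std(y)), 1e-12)
        penalty = 2.0 * sigma**2 * np.log(n)

    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    best = np.full(n + 1, np.inf)
    best[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for j in range(min_size, n + 1):
        i = np.arange(0, j - min_size + 1)
        m = j - i
        sse = (c2[j] - c2[i]) - (c1[j] - c1[i]) ** 2 / m
        cand = best[i] + penalty + sse
        # a changepoint may not fall inside the first min_size points
        cand[1:min(min_size, cand.size)] = np.inf
        k = int(np.argmin(cand))
        if cand[k] < best[j]:
            best[j] = cand[k]
            prev[j] = k
    cps = []
    j = n
    while j > 0:
        i = prev[j]
        if i > 0:
            cps.append(i)
        j = i
    return sorted(cps)


def segment_means(y, changepoints) -> np.ndarray:
    """Mean level of each segment defined by the changepoints."""
    y = np.asarray(y, dtype=float)
    bounds = [0, *changepoints, y.size]
    return np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
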