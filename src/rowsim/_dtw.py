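"""Normalised dynamic-time-warping core.

The dissimilarity between two sequences is the minimum over admissible
warping paths of (accumulated local cost) / (path length) — an "average
deviation" per matched sample pair.  Admissible paths start at (0, 0), end
at (n-1, m-1), and advance by unit diagonal/horizontal/vertical steps, so
the alignment is monotone (causal temporal order) with matched endpoints.

Minimising the *normalised* cost is a fractional program; it is solved
exactly by Dinkelbach iteration: repeatedly run the ordinary DTW dynamic
program on shifted local costs (d - lambda) and update lambda to the raw
cost/length ratio of the optimal shifted path.  Since there are finitely
many paths the iteration reaches the optimum in a handful of steps; the
value is independent of tie-breaking among equal-cost paths, unlike the
common "divide by the backtracked path length" convention.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["normalized_dtw", "local_cost_matrix"]


@njit(fastmath=False)
def _dp_backtrack(d: np.ndarray, lam: float) -> tuple[float, float, int]:
    """One DTW pass on shifted costs d - lam.

    Returns (optimal shifted cost, raw cost of an optimal path, its length).
    """
    n, m = d.shape
    acc = np.empty((n, m))
    acc[0, 0] = d[0, 0] - lam
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + d[0, j] - lam
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + d[i, 0] - lam
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = best + d[i, j] - lam
    i, j = n - 1, m - 1
    raw = d[i, j]
    length = 1
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            if diag <= up and diag <= left:
                i -= 1
                j -= 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        raw += d[i, j]
        length += 1
    return acc[n - 1, m - 1], raw, length


def local_cost_matrix(a: np.ndarray, b: np.ndarray,
                      temporal_shift_weight: float = 0.0) -> np.ndarray:
    """Pairwise Euclidean distances between samples of a (n,d) and b (m,d).

    A positive ``temporal_shift_weight`` adds a penalty proportional to the
    normalised-time offset of each matched pair; the evaluation pipeline
    runs with the weight at zero, scoring shape dissimilarity only.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(b, dtype=float).T).T
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("sequences must share dimensionality")
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("sequences must be non-empty")
    diff = a[:, None, :] - b[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=2))
    if temporal_shift_weight > 0.0:
        n, m = d.shape
        ta = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
        tb = np.linspace(0.0, 1.0, m) if m > 1 else np.zeros(1)
        d = d + temporal_shift_weight * np.abs(ta[:, None] - tb[None, :])
    return d


def normalized_dtw(d: np.ndarray, max_iter: int = 100) -> float:
    """Minimum over warping paths of path cost / path length."""
    d = np.ascontiguousarray(d, dtype=float)
    n, m = d.shape
    tol = 1e-14 * (n + m) * max(1.0, float(d.max(initial=0.0)))
    _, raw, length = _dp_backtrack(d, 0.0)
    lam = raw / length
    for _ in range(max_iter):
        shifted, raw, length = _dp_backtrack(d, lam)
        if shifted >= -tol:
            return float(lam)
        lam = raw / length
    return float(lam)
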