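"""Dynamic time warping with quaternion and Euclidean pointwise costs.

Two costs are used by the recognition pipeline:

* ``quaternion_cost(q1, q2) = 1 - |<q1, q2>|`` — the sign-invariant chordal
  dissimilarity of unit quaternions, used when aligning recordings for
  template averaging;
* plain Euclidean distance between 3-D direction vectors, used when
  classifying against spatial templates.

Reported distances are *normalized*: accumulated path cost divided by the
warping-path length, so distances are comparable across templates of
different lengths (required by the nearest-template rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

__all__ = ["WarpingPath", "quaternion_cost", "dtw", "dtw_distance"]


@dataclass(frozen=True)
class WarpingPath:
    """Monotone alignment between two sequences.

    ``pairs`` is an (L, 2) integer array starting at (0, 0), ending at
    (n-1, m-1), with steps in {(1,0), (0,1), (1,1)}.
    """

    pairs: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)


def quaternion_cost(q1: np.ndarray, q2: np.ndarray) -> float:
    """``1 - |q1 ∘ q2|`` where ``∘`` is the 4-D dot product.

    Zero iff the quaternions encode the same rotation (q and -q included);
    at most 1; symmetric.
    """
    return max(0.0, float(1.0 - abs(np.dot(np.asarray(q1, float), np.asarray(q2, float)))))


def _cost_matrix(a: np.ndarray, b: np.ndarray, cost) -> np.ndarray:
    if callable(cost):
        return np.array([[cost(x, y) for y in b] for x in a], dtype=float)
    if cost == "quaternion":
        return np.maximum(1.0 - np.abs(a @ b.T), 0.0)
    if cost == "euclidean":
        return cdist(a, b)
    raise ValueError(f"unknown cost {cost!r}")


@njit(cache=False)
def _accumulate(C):  # pragma: no cover - numba kernel
    n, m = C.shape
    D = np.empty((n, m))
    D[0, 0] = C[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + C[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + C[i, 0]
        for j in range(1, m):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = C[i, j] + best
    return D


@njit(cache=False)
def _backtrack(D):  # pragma: no cover - numba kernel
    n, m = D.shape
    path = np.empty((n + m, 2), dtype=np.int64)
    i, j = n - 1, m - 1
    k = n + m - 1
    path[k, 0] = i
    path[k, 1] = j
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            # tie-break: diagonal, then up, then left (deterministic)
            d = D[i - 1, j - 1]
            u = D[i - 1, j]
            l = D[i, j - 1]
            if d <= u and d <= l:
                i -= 1
                j -= 1
            elif u <= l:
                i -= 1
            else:
                j -= 1
        k -= 1
        path[k, 0] = i
        path[k, 1] = j
    return path[k:]


def dtw(
    a: np.ndarray,
    b: np.ndarray,
    cost: str | Callable = "quaternion",
) -> tuple[float, WarpingPath]:
    """Normalized DTW distance and optimal warping path.

    Parameters
    ----------
    a, b : (n, d) and (m, d) arrays of samples (quaternions or vectors).
    cost : "quaternion", "euclidean", or a callable ``(x, y) -> float``
        applied pairwise (slow; intended for testing).

    Returns
    -------
    distance : accumulated cost of the optimal monotone path divided by the
        path length.
    path : the optimal :class:`WarpingPath` (ties broken deterministically:
        diagonal preferred, then the first-sequence step).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("dtw requires non-empty sequences")
    C = _cost_matrix(a, b, cost)
    D = _accumulate(C)
    path = _backtrack(D)
    return float(D[-1, -1]) / len(path), WarpingPath(pairs=path)


def dtw_distance(a: np.ndarray, b: np.ndarray, cost: str | Callable = "quaternion") -> float:
    """Normalized DTW distance only (path computed for the normalizer)."""
    return dtw(a, b, cost)[0]
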