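"""Curve distances: Hausdorff, discrete Frechet, and an SSE evaluation metric.

The undirected Hausdorff distance,

    H(P, Q) = max( max_i min_j ||p_i - q_j||, max_j min_i ||q_j - p_i|| ),

is the worst-case disagreement between the two point sets and ignores
ordering.  The discrete Frechet distance,

    dF(P, Q) = min over monotone couplings (sigma, tau) of
               max_k ||p_sigma(k) - q_tau(k)||,

respects the temporal ordering of both curves (the "minimum leash length"
to walk both without backtracking) and is the primary criterion for FNR
selection; Hausdorff is retained to flag localized maximal deviations.
Both use the Euclidean point norm and always satisfy dF >= H for
same-order curves.

SSE, the sum of squared y-differences across shared grid points, is an
independent goodness-of-fit check only; it never drives FNR selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, directed_hausdorff

from .curves import ProjectedCurve

__all__ = [
    "DistancePair",
    "hausdorff",
    "discrete_frechet",
    "frechet_bruteforce",
    "sum_squared_errors",
    "distance_table",
]


@dataclass(frozen=True)
class DistancePair:
    """Hausdorff and discrete Frechet distances for one curve pair."""

    hausdorff: float
    frechet: float

    def __post_init__(self) -> None:
        if self.hausdorff < 0 or self.frechet < 0:
            raise ValueError("distances must be non-negative")


def _as_points(curve) -> np.ndarray:
    pts = curve.points if isinstance(curve, ProjectedCurve) else np.asarray(curve, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("curve must be a non-empty (m, 2) point array")
    return pts


def hausdorff(p, q) -> float:
    """Undirected Hausdorff distance between two planar point sequences."""
    pp, qq = _as_points(p), _as_points(q)
    return max(directed_hausdorff(pp, qq)[0], directed_hausdorff(qq, pp)[0])


def discrete_frechet(p, q) -> float:
    """Discrete Frechet distance via the standard O(m*m') dynamic program.

    c(i, j) = max( d(p_i, q_j), min(c(i-1, j), c(i, j-1), c(i-1, j-1)) )
    with c(0, 0) = d(p_0, q_0); the answer is c(m-1, m'-1).  Iterative
    table fill, row by row.
    """
    pp, qq = _as_points(p), _as_points(q)
    d = cdist(pp, qq)
    m, n = d.shape
    c = np.empty_like(d)
    c[0, 0] = d[0, 0]
    for j in range(1, n):
        c[0, j] = max(c[0, j - 1], d[0, j])
    for i in range(1, m):
        c[i, 0] = max(c[i - 1, 0], d[i, 0])
        for j in range(1, n):
            c[i, j] = max(d[i, j], min(c[i - 1, j], c[i, j - 1], c[i - 1, j - 1]))
    return float(c[m - 1, n - 1])


def frechet_bruteforce(p, q, max_len: int = 8) -> float:
    """Exhaustive-coupling discrete Frechet distance (test oracle).

    Enumerates every monotone coupling — every lattice path from (0, 0) to
    (m-1, n-1) with steps (1,0), (0,1), (1,1) — and returns the minimum
    over paths of the maximum paired distance.  Exponential; guarded to
    short curves.
    """
    pp, qq = _as_points(p), _as_points(q)
    m, n = pp.shape[0], qq.shape[0]
    if m > max_len or n > max_len:
        raise ValueError(f"brute force limited to curves of length <= {max_len}")
    d = cdist(pp, qq)

    best = np.inf

    def walk(i: int, j: int, leash: float) -> None:
        nonlocal best
        leash = max(leash, d[i, j])
        if leash >= best:
            return
        if i == m - 1 and j == n - 1:
            best = leash
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < m and nj < n:
                walk(ni, nj, leash)

    walk(0, 0, 0.0)
    return float(best)


def sum_squared_errors(p, q) -> float:
    """Sum over shared grid points of the squared y (Ne) difference.

    Requires both curves on the same grid: equal length and equal x
    coordinates.
    """
    pp, qq = _as_points(p), _as_points(q)
    if pp.shape[0] != qq.shape[0] or not np.allclose(pp[:, 0], qq[:, 0], rtol=0, atol=1e-12):
        raise ValueError("SSE requires both curves on the same time grid")
    diff = pp[:, 1] - qq[:, 1]
    return float(np.dot(diff, diff))


def distance_table(
    reference: ProjectedCurve, candidates: dict[float, ProjectedCurve]
) -> pd.DataFrame:
    """Score candidate curves against one reference.

    ``candidates`` maps an FNR label to its projected curve; the result has
    columns ``fnr``, ``hausdorff``, ``frechet``, ``sse``, sorted by fnr.
    """
    rows = [
        {
            "fnr": f,
            "hausdorff": hausdorff(reference, curve),
            "frechet": discrete_frechet(reference, curve),
            "sse": sum_squared_errors(reference, curve),
        }
        for f, curve in sorted(candidates.items())
    ]
    return pd.DataFrame(rows, columns=["fnr", "hausdorff", "frechet", "sse"])
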