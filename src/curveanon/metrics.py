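"""Similarity, distribution-distance and utility-loss metrics.

Three metric families drive the anonymization:

* the discrete Fréchet distance between curves (curve similarity, the
  ground distance of everything else),
* the Earth Mover's Distance between cluster histograms (t-closeness),
* the General Loss Metric and Median Relative Error (utility).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.optimize import linprog

from .curve_io import Curve, CurveSet, check_aligned
from .errors import CurveValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .hulls import Hull


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise curve-distance matrix with stable id order."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        object.__setattr__(self, "d", d)

    def index(self, curve_id: str) -> int:
        return self.ids.index(curve_id)

    def dist(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.d[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Discrete Fréchet distance
# ---------------------------------------------------------------------------

def _discrete_frechet_from_costs(cost: np.ndarray) -> float:
    """Discrete Fréchet distance given the full point-pair cost lattice.

    Anti-diagonal dynamic program: on diagonal ``i + j = const`` every
    cell depends only on the two previous diagonals, so each diagonal is
    vectorized. A virtual zero-cost start cell at the padded origin makes
    the first row/column recurrences fall out of the same update.
    """
    p, q = cost.shape
    ca = np.full((p + 1, q + 1), np.inf)
    ca[0, 0] = 0.0
    for k in range(2, p + q + 1):
        i_lo = max(1, k - q)
        i_hi = min(p, k - 1)
        i = np.arange(i_lo, i_hi + 1)
        j = k - i
        best = np.minimum(np.minimum(ca[i - 1, j], ca[i, j - 1]), ca[i - 1, j - 1])
        ca[i, j] = np.maximum(cost[i - 1, j - 1], best)
    return float(ca[p, q])


def _resampled_pair(a: Curve, b: Curve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Common grid and both value sequences; resamples only when grids differ."""
    if a.t.size == b.t.size and np.array_equal(a.t, b.t):
        return a.t, a.v, b.v
    grid = np.union1d(a.t, b.t)
    return grid, a.interp(grid), b.interp(grid)


def frechet_distance(
    a: Curve,
    b: Curve,
    time_scale: float = 0.0,
    value_scale: float = 1.0,
) -> float:
    """Discrete Fréchet distance between two aligned curves.

    The ground distance is Euclidean on ``(t * time_scale, v * value_scale)``.
    The default ``time_scale = 0`` compares values at coupled indices of
    the identically-resampled curves, sidestepping the unit mismatch
    between seconds and the signal unit; pass a positive scale to make
    time displacement contribute. Curves on different sampling grids are
    linearly resampled onto the union grid of the common frame first.
    """
    check_aligned(a, b)
    grid, va, vb = _resampled_pair(a, b)
    dv = np.abs(va[:, None] - vb[None, :]) * value_scale
    if time_scale == 0.0:
        cost = dv
    else:
        dt = (grid[:, None] - grid[None, :]) * time_scale
        cost = np.hypot(dt, dv)
    return _discrete_frechet_from_costs(cost)


def pairwise_distances(
    cs: CurveSet,
    time_scale: float = 0.0,
    value_scale: float = 1.0,
) -> DistanceMatrix:
    """All-pairs Fréchet distance matrix over an aligned curve set."""
    curves = list(cs)
    n = len(curves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = frechet_distance(
                curves[i], curves[j], time_scale, value_scale
            )
    return DistanceMatrix(tuple(c.curve_id for c in curves), d)


# ---------------------------------------------------------------------------
# Earth Mover's Distance
# ---------------------------------------------------------------------------

def emd(p: np.ndarray, q: np.ndarray, ground: np.ndarray) -> float:
    """Earth Mover's Distance between two histograms over the same bins.

    Both histograms are normalized to unit mass, so the optimal transport
    cost equals the work per unit flow. Solved exactly as a transportation
    linear program; bin counts are small here (tens at most).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    ground = np.asarray(ground, dtype=float)
    if p.ndim != 1 or q.ndim != 1 or p.size != q.size:
        raise ValueError("histograms must be 1-D over the same cluster index set")
    if ground.shape != (p.size, q.size):
        raise ValueError("ground distance matrix shape mismatch")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("histogram masses must be non-negative")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("empty histogram: each side needs positive total mass")
    p = p / p.sum()
    q = q / q.sum()
    if np.allclose(p, q, rtol=0.0, atol=1e-15):
        return 0.0
    n = p.size
    c = ground.reshape(-1)
    # Row sums = p, column sums = q; drop the last (redundant) constraint.
    a_eq = np.zeros((2 * n - 1, n * n))
    for i in range(n):
        a_eq[i, i * n : (i + 1) * n] = 1.0
    for j in range(n - 1):
        a_eq[n + j, j::n] = 1.0
    b_eq = np.concatenate([p, q[:-1]])
    res = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - degenerate numerical failure
        raise RuntimeError(f"transportation LP failed: {res.message}")
    return float(max(res.fun, 0.0))


# ---------------------------------------------------------------------------
# Utility metrics
# ---------------------------------------------------------------------------

def glm_info_loss(
    hull: "Hull",
    value_domain: tuple[float, float],
    member_count: int,
) -> float:
    """General Loss Metric: fraction of the value domain spanned by a hull.

    The mean, over hull grid points, of ``(upper - lower)`` normalized by
    the dataset's value-domain width. A single-member class carries no
    generalization and loses nothing, hence 0. A degenerate domain
    (all values identical) is defined as loss 0 with a warning.
    """
    if member_count == 1:
        return 0.0
    width = value_domain[1] - value_domain[0]
    if width <= 0:
        warnings.warn(
            "degenerate value domain (min == max); information loss defined as 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.mean(hull.upper - hull.lower) / width)


def glm_from_envelope(
    lower: np.ndarray,
    upper: np.ndarray,
    value_domain: tuple[float, float],
    member_count: int,
) -> float:
    """GLM on raw envelope arrays (used by the builder's incremental fill)."""
    if member_count <= 1:
        return 0.0
    width = value_domain[1] - value_domain[0]
    if width <= 0:
        return 0.0
    return float(np.mean(upper - lower) / width)


def median_relative_error(
    members: Sequence[Curve],
    hull: "Hull",
    interpolation: str = "linear",
) -> float:
    """Median, over members and hull grid times, of the distance to the
    nearer hull bound.

    Member values are interpolated at the hull grid (the hull resolution
    need not match the member sampling). Members that lie on a bound
    contribute zeros.
    """
    members = list(members)
    if not members:
        raise CurveValidationError("median_relative_error over an empty class")
    errors = []
    for m in members:
        vals = m.interp(hull.grid, mode=interpolation)
        errors.append(np.minimum(np.abs(vals - hull.lower), np.abs(hull.upper - vals)))
    return float(np.median(np.concatenate(errors)))
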