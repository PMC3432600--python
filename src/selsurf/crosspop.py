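"""Cross-population regression of selection strength on competition.

Tests whether the intensity of quadratic selection (gamma, one value per
pond collection) is predicted by intraspecific competition (per-capita
resource abundance or conspecific density) across collections.  Collections
with more tadpoles measured give more reliable differentials, so the
regression is weighted — by the square root of each collection's sample
size by default, with plain-``n`` weighting available as a sensitivity
switch.

Ponds sampled in several years contribute several collections; to guard
against this temporal pseudo-replication, a pond-level bootstrap draws one
collection per unique pond per replicate, refits the weighted regression,
and summarizes the replicate slopes by their median and percentile 95%
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["CrossPopResult", "weighted_regression", "pond_bootstrap"]

_WEIGHT_SCHEMES = ("sqrt_n", "n")


@dataclass(frozen=True)
class CrossPopResult:
    slope: float
    intercept: float
    F: float                    # F statistic for the slope, (1, n-2) df
    p: float
    n_collections: int
    weights: np.ndarray
    boot_median: float = float("nan")
    boot_ci: tuple[float, float] = (float("nan"), float("nan"))
    boot_slopes: "np.ndarray | None" = None


def _weights(n: np.ndarray, scheme: str) -> np.ndarray:
    if scheme not in _WEIGHT_SCHEMES:
        raise ValueError(f"weight scheme must be one of {_WEIGHT_SCHEMES}")
    n = np.asarray(n, dtype=float)
    if (n <= 0).any():
        raise ValueError("sample sizes must be positive")
    return np.sqrt(n) if scheme == "sqrt_n" else n


def _wls_slope(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Closed-form weighted least squares slope and intercept."""
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx == 0:
        raise ValueError("constant predictor: slope undefined")
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    return float(slope), float(ybar - slope * xbar)


def weighted_regression(
    gamma: np.ndarray,
    predictor: np.ndarray,
    n: np.ndarray,
    weight_scheme: str = "sqrt_n",
) -> CrossPopResult:
    """Weighted least-squares regression of gamma on a competition measure.

    Returns the slope, its F statistic on (1, n_collections - 2) df and the
    two-sided P-value.  A perfect fit (zero residual sum of squares) is
    reported with the largest finite F and a P-value at the smallest
    positive float rather than a division-by-zero.
    """
    y = np.asarray(gamma, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.size != x.size or y.size != np.asarray(n).size:
        raise ValueError("gamma, predictor and n must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 collections")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope undefined")
    w = _weights(np.asarray(n), weight_scheme)

    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    F = float(res.tvalues[1] ** 2)
    p = float(res.pvalues[1])
    if not np.isfinite(F):
        F = float(np.finfo(float).max)
        p = float(np.nextafter(0.0, 1.0))
    return CrossPopResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        F=F,
        p=p,
        n_collections=int(y.size),
        weights=w,
    )


def pond_bootstrap(
    gamma: np.ndarray,
    predictor: np.ndarray,
    n: np.ndarray,
    pond_of: "np.ndarray | list",
    reps: int = 1000,
    seed: int = 0,
    weight_scheme: str = "sqrt_n",
) -> CrossPopResult:
    """Pond-level bootstrap of the weighted regression slope.

    ``pond_of`` maps each collection to its unique physical pond.  Each
    replicate draws one collection uniformly from every unique pond, refits
    the weighted regression on those points (each with its own weight), and
    records the slope.  Returns the full-sample fit augmented with the
    bootstrap median and percentile 2.5/97.5 interval; the association is
    deemed significant when the interval excludes zero.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    y = np.asarray(gamma, dtype=float)
    x = np.asarray(predictor, dtype=float)
    w = _weights(np.asarray(n), weight_scheme)
    ponds = np.asarray(pond_of)
    if not (y.size == x.size == w.size == ponds.size):
        raise ValueError("all inputs must have one entry per collection")

    groups = [np.flatnonzero(ponds == p) for p in pd.unique(ponds)]
    if any(g.size == 0 for g in groups):  # pragma: no cover - unique() precludes
        raise ValueError("a unique pond has zero collections")

    rng = np.random.default_rng(seed)
    slopes = np.empty(reps)
    for r in range(reps):
        idx = np.array([g[rng.integers(g.size)] for g in groups])
        slopes[r], _ = _wls_slope(y[idx], x[idx], w[idx])

    full = weighted_regression(y, x, np.asarray(n), weight_scheme)
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return CrossPopResult(
        slope=full.slope,
        intercept=full.intercept,
        F=full.F,
        p=full.p,
        n_collections=full.n_collections,
        weights=full.weights,
        boot_median=float(np.median(slopes)),
        boot_ci=(float(lo), float(hi)),
        boot_slopes=slopes,
    )
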