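"""Standardized selection differentials from relative fitness regressions.

Fitness is proxied by larval body size: relative fitness of individual *i* is
``w_i = ln(SVL_i) / mean ln SVL`` so that mean(w) = 1.  Selection on the
morphological index ``z`` (unit SD) is estimated by two separate ordinary
least-squares regressions:

* linear:    ``w ~ a + beta * z``  — the standardized linear (directional)
  selection differential is the slope ``beta``;
* quadratic: ``w ~ a + b1 * z + c * z^2`` — the standardized quadratic
  selection differential is ``gamma = 2c`` (the doubling makes the
  coefficient comparable to the curvature of the individual fitness
  surface), with its SE doubled accordingly; the t statistic is unchanged.

A significantly positive gamma is necessary but not sufficient evidence of
disruptive selection: classification additionally requires an interior
fitness minimum on the nonparametric fitness surface (see
:mod:`selsurf.surface`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SelectionDifferentials",
    "ModeClassification",
    "relative_fitness",
    "estimate_differentials",
    "classify_mode",
]


@dataclass(frozen=True)
class SelectionDifferentials:
    beta: float
    se_beta: float
    t_beta: float
    p_beta: float
    gamma: float          # 2 x raw quadratic coefficient
    se_gamma: float       # 2 x raw SE
    t_gamma: float
    p_gamma: float
    n: int
    # linear term of the quadratic model, kept for diagnostics; beta above
    # always comes from the separate linear-only regression
    linear_term_quadratic_model: float = float("nan")


@dataclass(frozen=True)
class ModeClassification:
    """Mode of quadratic selection plus an orthogonal directional flag.

    mode is one of "disruptive", "stabilizing", "none"; directional is the
    sign of a significant beta (+1 carnivore-favoring, -1 omnivore-favoring,
    0 when beta is not significant).
    """

    mode: str
    directional: int


def relative_fitness(records: "pd.DataFrame | np.ndarray") -> np.ndarray:
    """Relative fitness w_i = ln(SVL_i) / mean_j ln(SVL_j); mean(w) = 1."""
    if isinstance(records, pd.DataFrame):
        svl = records["SVL_mm"].to_numpy(dtype=float)
    else:
        svl = np.asarray(records, dtype=float)
    if (svl <= 0).any():
        raise ValueError("SVL must be positive")
    ln = np.log(svl)
    mean_ln = ln.mean()
    if mean_ln <= 0:
        raise ValueError(
            "mean ln SVL <= 0: the relative-fitness ratio convention requires "
            "SVL comfortably above 1 mm"
        )
    return ln / mean_ln


def estimate_differentials(index: np.ndarray, w: np.ndarray) -> SelectionDifferentials:
    """Standardized linear and quadratic selection differentials.

    Fits the two separate regressions described in the module docstring and
    applies the gamma-doubling convention exactly: gamma = 2c and
    se_gamma = 2 SE(c), so t_gamma equals the raw coefficient's t ratio.
    """
    z = np.asarray(index, dtype=float)
    w = np.asarray(w, dtype=float)
    if z.shape != w.shape:
        raise ValueError("index and fitness must have equal length")
    n = z.size
    if n < 4:
        raise ValueError("need at least 4 individuals")
    if z.std(ddof=1) == 0:
        raise ValueError("singular design: trait scores are constant")

    lin = sm.OLS(w, sm.add_constant(z)).fit()
    quad = sm.OLS(w, sm.add_constant(np.column_stack([z, z**2]))).fit()

    c, se_c = quad.params[2], quad.bse[2]
    return SelectionDifferentials(
        beta=float(lin.params[1]),
        se_beta=float(lin.bse[1]),
        t_beta=float(lin.tvalues[1]),
        p_beta=float(lin.pvalues[1]),
        gamma=float(2.0 * c),
        se_gamma=float(2.0 * se_c),
        t_gamma=float(quad.tvalues[2]),
        p_gamma=float(quad.pvalues[2]),
        n=int(n),
        linear_term_quadratic_model=float(quad.params[1]),
    )


def classify_mode(
    est: SelectionDifferentials,
    surface: "object | None",
    alpha: float = 0.05,
) -> ModeClassification:
    """Classify the mode of selection for one pond.

    "disruptive" requires a significantly positive gamma AND an interior
    fitness minimum on the spline surface; "stabilizing" a significantly
    negative gamma AND an interior maximum.  Where the spline extremum flag
    and the constrained-regression (Mitchell-Olds & Shaw) test disagree, the
    spline flag governs — the nonparametric surface is robust to the
    parametric test's assumptions.  The directional flag is set from the
    linear differential independently of the quadratic mode.

    ``surface`` may be a :class:`selsurf.surface.SurfaceResult` or None; with
    no surface available the extremum requirement cannot be checked and the
    mode falls back to sign-and-significance of gamma alone.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    sig_gamma = est.p_gamma < alpha
    interior_min = getattr(surface, "interior_min", True)
    interior_max = getattr(surface, "interior_max", True)

    if sig_gamma and est.gamma > 0 and interior_min:
        mode = "disruptive"
    elif sig_gamma and est.gamma < 0 and interior_max:
        mode = "stabilizing"
    else:
        mode = "none"

    directional = int(np.sign(est.beta)) if est.p_beta < alpha else 0
    return ModeClassification(mode=mode, directional=directional)
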