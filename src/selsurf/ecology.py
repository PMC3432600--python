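"""Intraspecific-competition measures from pond field surveys.

Each pond survey records ordinal conspecific tadpole density (1 = low,
2 = moderate, 3 = high), ordinal fairy-shrimp density (1-3) and fractional
vegetative cover around the pond (a proxy for detritus availability).
Competition intensity is summarized by per-capita resource abundance:
the sum of the shrimp and detritus categories divided by the tadpole-density
category.  Lower per-capita resource (and higher conspecific density) means
more intense intraspecific competition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompetitionScore",
    "categorize_cover",
    "per_capita_resource",
    "competition_table",
    "summarize_samples",
]


@dataclass(frozen=True)
class CompetitionScore:
    detritus_category: int      # 1-3, from vegetative cover
    resource_sum: int           # shrimp + detritus, 2-6
    per_capita_resource: float  # resource_sum / tadpole_density, in [2/3, 6]
    conspecific_density: int    # ordinal 1-3


def categorize_cover(cover: float) -> int:
    """Map fractional vegetative cover to the ordinal detritus category:
    low (<= 33%) -> 1, moderate (<= 66%) -> 2, high -> 3.  Boundary values
    fall in the lower category."""
    cover = float(cover)
    if not 0.0 <= cover <= 1.0:
        raise ValueError("cover must be a fraction in [0, 1]")
    if cover <= 0.33:
        return 1
    if cover <= 0.66:
        return 2
    return 3


def _check_ordinal(value: int, name: str) -> int:
    value = int(value)
    if value not in (1, 2, 3):
        raise ValueError(f"{name} must be an ordinal category in {{1, 2, 3}}")
    return value


def per_capita_resource(rec: "pd.Series | dict") -> CompetitionScore:
    """Per-capita resource score for one pond record (needs fields
    ``tadpole_density``, ``shrimp_density``, ``cover``)."""
    density = _check_ordinal(rec["tadpole_density"], "tadpole_density")
    shrimp = _check_ordinal(rec["shrimp_density"], "shrimp_density")
    detritus = categorize_cover(rec["cover"])
    resource_sum = shrimp + detritus
    return CompetitionScore(
        detritus_category=detritus,
        resource_sum=resource_sum,
        per_capita_resource=resource_sum / density,
        conspecific_density=density,
    )


def competition_table(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized competition scores for a pond table; returns the input
    plus ``detritus_category``, ``resource_sum`` and ``per_capita_resource``
    columns."""
    scores = [per_capita_resource(row) for _, row in records.iterrows()]
    out = records.copy()
    out["detritus_category"] = [s.detritus_category for s in scores]
    out["resource_sum"] = [s.resource_sum for s in scores]
    out["per_capita_resource"] = [s.per_capita_resource for s in scores]
    return out


def summarize_samples(records: pd.DataFrame) -> dict:
    """Median, min and max collection sample size across ponds."""
    if len(records) < 1:
        raise ValueError("need at least one pond record")
    n = records["n"].to_numpy(dtype=float)
    return {
        "median": float(np.median(n)),
        "min": float(n.min()),
        "max": float(n.max()),
    }
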