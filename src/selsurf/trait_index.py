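"""Composite trophic-morphology index (per-pond PC1).

The resource-use phenotype of a tadpole is summarized by the first principal
component of three variables measured on each individual: the ordinal
mouthpart score (MP), the residual of ln jaw-muscle width on ln body length
(size-corrected OH), and the denticle-row count (DR).  The PCA uses the
correlation matrix, is computed separately for each pond, and the scores are
standardized to unit SD.  The sign is fixed so that the MP loading is
positive: larger index values mean more carnivore-like tadpoles (bigger jaw
muscles for their size, fewer denticle rows, more serrated mouthparts).

When DR is unavailable for a collection the index falls back to a
two-variable PCA of MP and residual OH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MorphIndexResult", "allometric_residuals", "morph_index"]


@dataclass(frozen=True)
class MorphIndexResult:
    """Per-pond morphological index.

    Attributes
    ----------
    scores : ndarray
        PC1 score per individual, standardized to sample SD 1.
    loadings : DataFrame
        Unit-norm eigenvector loadings, variables x components.
    variance_explained : ndarray
        Fraction of total (correlation-matrix) variance per component.
    variables_used : tuple of str
        Which of ("MP", "residual_OH", "DR") entered the PCA.
    allometry : tuple (intercept, slope)
        OLS fit of ln OH on ln SVL used for size correction.
    """

    scores: np.ndarray
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    variables_used: tuple[str, ...]
    allometry: tuple[float, float]


def _validate_records(records: pd.DataFrame) -> None:
    for col in ("SVL_mm", "OH_mm", "MP"):
        if col not in records.columns:
            raise ValueError(f"records missing required column {col!r}")
    if (records["SVL_mm"] <= 0).any() or (records["OH_mm"] <= 0).any():
        raise ValueError("SVL and OH must be strictly positive (logs required)")
    mp = records["MP"].to_numpy()
    if not np.isin(mp, [1, 2, 3, 4, 5]).all():
        raise ValueError("MP scores must be ordinal integers in 1..5")


def allometric_residuals(records: pd.DataFrame) -> np.ndarray:
    """Residuals of the within-pond OLS regression of ln OH on ln SVL.

    These residuals measure jaw-muscle width corrected for body size; by OLS
    construction they sum to zero and are uncorrelated with ln SVL.
    """
    _validate_records(records)
    if len(records) < 3:
        raise ValueError("need at least 3 records to fit the allometry")
    x = np.log(records["SVL_mm"].to_numpy(dtype=float))
    y = np.log(records["OH_mm"].to_numpy(dtype=float))
    if np.ptp(x) == 0:
        raise ValueError("all SVL equal: allometric slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return y - (intercept + slope * x)


def _allometry_fit(records: pd.DataFrame) -> tuple[float, float]:
    x = np.log(records["SVL_mm"].to_numpy(dtype=float))
    y = np.log(records["OH_mm"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def morph_index(records: pd.DataFrame) -> MorphIndexResult:
    """Compute the per-pond morphological index (PC1 of MP, residual OH, DR).

    If any DR value in the pond is missing, DR is dropped for the whole pond
    and the two-variable (MP, residual OH) index is computed instead.
    Raises if any included variable has zero variance (the correlation
    matrix would be undefined).
    """
    _validate_records(records)
    if len(records) < 4:
        raise ValueError("need at least 4 records for the index PCA")

    res_oh = allometric_residuals(records)
    columns: dict[str, np.ndarray] = {
        "MP": records["MP"].to_numpy(dtype=float),
        "residual_OH": res_oh,
    }
    use_dr = "DR" in records.columns and not records["DR"].isna().any()
    if use_dr:
        columns["DR"] = records["DR"].to_numpy(dtype=float)

    names = tuple(columns)
    X = np.column_stack([columns[name] for name in names])
    sds = X.std(axis=0, ddof=1)
    for name, sd in zip(names, sds):
        if sd == 0:
            raise ValueError(f"variable {name!r} has zero variance in this pond")
    Z = (X - X.mean(axis=0)) / sds

    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    # Sign convention: MP loads positively on every component so that larger
    # scores mean more carnivore-like morphology on PC1.
    mp_row = names.index("MP")
    flip = np.where(eigvecs[mp_row, :] < 0, -1.0, 1.0)
    eigvecs = eigvecs * flip

    scores = Z @ eigvecs[:, 0]
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate PC1: zero score variance")
    scores = scores / sd

    loadings = pd.DataFrame(
        eigvecs,
        index=list(names),
        columns=[f"PC{i + 1}" for i in range(len(names))],
    )
    return MorphIndexResult(
        scores=scores,
        loadings=loadings,
        variance_explained=np.clip(eigvals, 0.0, None) / len(names),
        variables_used=names,
        allometry=_allometry_fit(records),
    )
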