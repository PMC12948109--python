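"""Phenotype preparation: outlier exclusion, covariate adjustment, z-scoring.

The common workflow applied to every trait before Haseman-Elston analysis:

1. values more than 5 SD from the trait mean are set missing (single pass);
2. the trait is regressed on age (numeric) plus sex / generation / diet
   (indicator-coded) by ordinary least squares;
3. residuals are z-score normalized (mean 0, SD 1, sample denominator).

Diet may be categorical (intervention groups) or numeric (days on diet).
Individuals lacking a required covariate are set missing for that trait.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["remove_outliers", "adjust_and_normalize", "zscore", "prepare_table"]

OUTLIER_SD = 5.0


def zscore(y: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (n-1 denominator), preserving NaNs."""
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    out = np.full_like(y, np.nan)
    sd = np.std(y[mask], ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot z-score")
    out[mask] = (y[mask] - np.mean(y[mask])) / sd
    return out


def remove_outliers(y: np.ndarray, k: float = OUTLIER_SD) -> np.ndarray:
    """Set values differing from the mean by more than k SDs to missing.

    Mean and SD are computed once over the non-missing values; the rule is
    applied in a single pass (no re-iteration after exclusion).
    """
    y = np.asarray(y, dtype=float).copy()
    mask = np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    mu, sd = y[mask].mean(), y[mask].std(ddof=1)
    if sd > 0:
        y[mask & (np.abs(y - mu) > k * sd)] = np.nan
    return y


def _design_matrix(covars: pd.DataFrame, diet_numeric: bool) -> tuple[np.ndarray, list[str]]:
    """Intercept + numeric age/diet + dummy-coded factors; single-level factors dropped."""
    cols: list[np.ndarray] = [np.ones(len(covars))]
    names = ["intercept"]
    for name in covars.columns:
        col = covars[name]
        numeric = name == "age" or (name == "diet" and diet_numeric) or (
            pd.api.types.is_numeric_dtype(col) and name not in ("sex", "generation", "diet")
        )
        if numeric:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            levels = pd.unique(col.astype(str))
            if len(levels) < 2:
                continue  # constant factor carries no information
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
    return np.column_stack(cols), names


def adjust_and_normalize(
    y: np.ndarray,
    covars: pd.DataFrame,
    diet_numeric: bool = False,
) -> np.ndarray:
    """OLS-adjust a trait for covariates and z-score the residuals.

    Fits ``y ~ age + sex + generation + diet`` (whichever columns are present
    in ``covars``) on the non-missing observations, with categorical
    covariates indicator-coded.  Individuals with a missing covariate are set
    missing.  Returns the residuals standardized to mean 0, SD 1, with NaN at
    excluded positions.
    """
    y = np.asarray(y, dtype=float)
    if len(covars) != len(y):
        raise ValueError("covariate table must have one row per individual")
    usable = np.isfinite(y) & ~covars.isna().any(axis=1).to_numpy()
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable observations after missingness")
    X, names = _design_matrix(covars.loc[usable], diet_numeric)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j in range(1, X.shape[1]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y[usable], rcond=None)
    resid = y[usable] - X @ beta
    out = np.full_like(y, np.nan)
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("residuals have zero variance")
    out[usable] = (resid - resid.mean()) / sd
    return out


def prepare_table(
    phenos: pd.DataFrame,
    covars: pd.DataFrame,
    diet_numeric: bool = False,
    outlier_sd: float = OUTLIER_SD,
) -> pd.DataFrame:
    """Apply the full workflow (outliers -> adjust -> z-score) to every trait."""
    covars = covars.loc[phenos.index]
    out = {}
    for trait in phenos.columns:
        y = remove_outliers(phenos[trait].to_numpy(dtype=float), k=outlier_sd)
        out[trait] = adjust_and_normalize(y, covars, diet_numeric=diet_numeric)
    return pd.DataFrame(out, index=phenos.index)
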