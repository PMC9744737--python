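"""Model evaluation: Spearman, R-squared, Lin's concordance, cohort balance.

R-squared is the squared Pearson correlation of the simple observed-vs-
predicted regression (symmetric in its arguments).  Lin's concordance
correlation coefficient (CCC) measures agreement about the identity line
and uses population (divide-by-n) moments, Lin's original estimator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .screen import bh_adjust, spearman

logger = logging.getLogger("csfseverity")

__all__ = ["concordance_ccc", "evaluate_predictions", "validate_progression",
           "compare_cohorts"]


def concordance_ccc(x, y, sample_moments: bool = False) -> float:
    """Lin's CCC: 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input to CCC; returning NaN")
        return float("nan")
    ddof = 1 if sample_moments else 0
    sx = x.var(ddof=ddof)
    sy = y.var(ddof=ddof)
    n = x.size
    sxy = ((x - x.mean()) * (y - y.mean())).sum() / (n - ddof)
    return float(2.0 * sxy / (sx + sy + (x.mean() - y.mean()) ** 2))


def evaluate_predictions(observed, predicted, outcome_name: str = "",
                         cohort: str = "") -> dict:
    """Spearman rho + p, R^2 (squared Pearson), and CCC for paired values."""
    x = np.asarray(observed, float)
    y = np.asarray(predicted, float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaNs in observed/predicted values")
    if x.size < 4:
        raise ValueError("need n >= 4 paired values")
    rho, p = spearman(x, y)
    r = np.corrcoef(x, y)[0, 1]
    return {"outcome": outcome_name, "cohort": cohort, "n": int(x.size),
            "spearman_rho": rho, "spearman_p": p,
            "r_squared": float(r**2), "ccc": concordance_ccc(x, y)}


def validate_progression(predictors: pd.DataFrame, slopes: pd.Series) -> pd.DataFrame:
    """Spearman correlation of each predictor with progression slopes, BH-adjusted.

    Predictors may include model predictions and clinical severity scales;
    pairs with fewer than 4 complete observations are skipped with a warning.
    """
    rows = []
    for name in predictors.columns:
        x = predictors[name]
        keep = x.notna() & slopes.notna()
        if int(keep.sum()) < 4:
            logger.warning("predictor %r: < 4 paired values; skipped", name)
            continue
        rho, p = spearman(x[keep].to_numpy(), slopes[keep].to_numpy())
        rows.append({"predictor": name, "n": int(keep.sum()),
                     "spearman_rho": rho, "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    return out


def compare_cohorts(metadata_train: pd.DataFrame, metadata_valid: pd.DataFrame,
                    quantitative: tuple = ("age", "edss", "msdss_baseline")) -> pd.DataFrame:
    """Cohort-balance tests: Yates-corrected 2x2 chi-square for sex, two-sided
    rank-sum for quantitative variables present in both tables."""
    if len(metadata_train) == 0 or len(metadata_valid) == 0:
        raise ValueError("both cohorts must be non-empty")
    rows = []
    table = np.array([
        [(metadata_train["sex"] == "F").sum(), (metadata_train["sex"] == "M").sum()],
        [(metadata_valid["sex"] == "F").sum(), (metadata_valid["sex"] == "M").sum()],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty sex category in one cohort")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    rows.append({"variable": "sex", "test": "chi-square", "statistic": float(chi2),
                 "p_value": float(p)})
    for var in quantitative:
        if var not in metadata_train.columns or var not in metadata_valid.columns:
            continue
        a = metadata_train[var].dropna().to_numpy(float)
        b = metadata_valid[var].dropna().to_numpy(float)
        if len(a) == 0 or len(b) == 0:
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"variable": var, "test": "rank-sum", "statistic": float(stat),
                     "p_value": float(p)})
    return pd.DataFrame(rows)
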