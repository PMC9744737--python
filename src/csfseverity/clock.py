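"""Proteomic aging clock: elastic net on HV CSF, applied to MS.

The clock regresses chronological age on standardized analyte values in the
healthy-volunteer cohort (elastic net, balanced L1/L2 mixing, penalty chosen
by leave-one-out cross-validation with the one-standard-error rule — the HV
cohort is too small for stable k-fold).  Standardization parameters come
from the training data only; predictions for MS samples are pure functions
of the frozen model.  Delta-age (predicted minus observed) contrasts between
diagnostic groups use two-sided rank-sum tests with BH adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet

from .screen import bh_adjust

logger = logging.getLogger("csfseverity")

__all__ = ["AgingClockModel", "train_clock", "predict_age", "compare_delta_age"]


@dataclass
class AgingClockModel:
    analyte_ids: list
    coefficients: np.ndarray        # on standardized inputs
    intercept: float
    l1_ratio: float
    alpha: float
    train_r2: float
    means: np.ndarray
    sds: np.ndarray


def _loo_mse(X: np.ndarray, y: np.ndarray, alpha: float, l1_ratio: float) -> np.ndarray:
    n = len(y)
    errs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        m = idx != i
        en = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=20000, tol=1e-5)
        en.fit(X[m], y[m])
        errs[i] = (en.predict(X[i:i + 1])[0] - y[i]) ** 2
    return errs


def train_clock(hv_panel: pd.DataFrame, hv_ages: pd.Series | np.ndarray,
                l1_ratio: float = 0.5, n_alphas: int = 30) -> AgingClockModel:
    """Fit the age model on HV data with LOO-CV penalty selection (1-SE rule)."""
    y = np.asarray(hv_ages, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("age vector is constant")
    if len(y) < 10:
        raise ValueError(f"need >= 10 HV samples, got {len(y)}")
    X = hv_panel.to_numpy(float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Z = (X - means) / sds

    # alpha grid on the standard sklearn scale (alpha_max zeroes all coefs)
    yc = y - y.mean()
    alpha_max = np.max(np.abs(Z.T @ yc)) / (len(y) * max(l1_ratio, 1e-3))
    alphas = np.geomspace(alpha_max, alpha_max * 1e-4, n_alphas)
    mse_mean = np.empty(n_alphas)
    mse_se = np.empty(n_alphas)
    for k, a in enumerate(alphas):
        errs = _loo_mse(Z, y, a, l1_ratio)
        mse_mean[k] = errs.mean()
        mse_se[k] = errs.std(ddof=1) / np.sqrt(len(errs))
    i_min = int(np.argmin(mse_mean))
    thr = mse_mean[i_min] + mse_se[i_min]
    # largest penalty (smallest index, grid is decreasing) within one SE
    i_sel = int(np.flatnonzero(mse_mean <= thr)[0])
    alpha = float(alphas[i_sel])

    en = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=20000)
    en.fit(Z, y)
    pred = en.predict(Z)
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ((y - pred) ** 2).sum() / sst
    logger.info("aging clock: alpha=%.4g, %d nonzero coefficients, in-sample R2=%.3f",
                alpha, int((en.coef_ != 0).sum()), r2)
    return AgingClockModel(analyte_ids=list(hv_panel.columns),
                           coefficients=en.coef_.copy(), intercept=float(en.intercept_),
                           l1_ratio=l1_ratio, alpha=alpha, train_r2=float(r2),
                           means=means, sds=sds)


def predict_age(model: AgingClockModel, panel: pd.DataFrame) -> pd.Series:
    """Linear score on standardized inputs + intercept, one value per sample."""
    missing = [a for a in model.analyte_ids if a not in panel.columns]
    if missing:
        raise KeyError(f"panel missing clock analytes: {missing[:5]}")
    X = panel[model.analyte_ids].to_numpy(float)
    Z = (X - model.means) / model.sds
    return pd.Series(Z @ model.coefficients + model.intercept,
                     index=panel.index, name="predicted_age")


def compare_delta_age(predicted: pd.Series, observed: pd.Series,
                      groups: pd.Series) -> pd.DataFrame:
    """Pairwise rank-sum contrasts of delta-age between groups, BH-adjusted."""
    delta = predicted - np.asarray(observed, float)
    labels = []
    for g in pd.unique(groups):
        if (groups == g).sum() < 2:
            logger.warning("group %r has n < 2; excluded from contrasts", g)
        else:
            labels.append(g)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups with n >= 2")
    rows = []
    for a, b in combinations(labels, 2):
        da = delta[groups == a].to_numpy()
        db = delta[groups == b].to_numpy()
        stat, p = stats.mannwhitneyu(da, db, alternative="two-sided")
        rows.append({"group_a": a, "group_b": b,
                     "median_delta_a": float(np.median(da)),
                     "median_delta_b": float(np.median(db)),
                     "statistic": float(stat), "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    return out
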