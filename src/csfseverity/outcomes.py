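"""Severity outcomes: brain-volume-deficit residuals and severity stability.

The brain volume deficit (BVD) severity outcome is the residual of
(1 - BPFr) regressed on age over the MS baseline cohort: positive values
mark patients who lost more brain tissue than their age peers.

Intra-individual stability of a longitudinal severity measure is quantified
by the one-way random-effects intraclass correlation coefficient (ICC),
which compares the fluctuation of repeated measurements within patients to
the variance between patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("csfseverity")

__all__ = ["compute_bvd_severity", "compute_icc", "BVDFit"]


@dataclass
class BVDFit:
    residuals: pd.Series
    slope: float
    intercept: float
    t_statistic: float
    p_value: float
    dof: int


def compute_bvd_severity(bpfr: pd.Series, age: pd.Series,
                         ms_baseline_mask: pd.Series) -> BVDFit:
    """OLS of (1 - BPFr) on age over the MS baseline cohort; residuals out.

    BPFr must lie in (0, 1); the fitted age slope, t-statistic and p-value
    are retained (a positive slope means increasing deficit with age).
    """
    mask = ms_baseline_mask.astype(bool)
    b = bpfr[mask].to_numpy(float)
    a = age[mask].to_numpy(float)
    if ((b <= 0) | (b >= 1)).any():
        raise ValueError("BPFr values must lie in (0, 1)")
    if np.ptp(a) == 0:
        raise ValueError("age is constant over the fitting cohort")
    y = 1.0 - b
    n = len(y)
    X = np.column_stack([np.ones(n), a])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 2
    sigma2 = (resid**2).sum() / dof
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    t = beta[1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return BVDFit(residuals=pd.Series(resid, index=bpfr.index[mask], name="bvd_severity"),
                  slope=float(beta[1]), intercept=float(beta[0]),
                  t_statistic=float(t), p_value=float(p), dof=dof)


def compute_icc(long_table: pd.DataFrame,
                subject_col: str = "subject_id",
                value_col: str = "severity") -> float:
    """One-way random-effects ICC from the one-way ANOVA decomposition.

    ICC = (MSB - MSW) / (MSB + (k0 - 1) * MSW), with the standard
    unbalanced-design group size k0 = (N - sum(k_i^2)/N) / (n_subjects - 1).
    The estimate may be <= 0 when the between-subject variance estimate is
    non-positive; if both mean squares are zero the result is NaN.
    """
    groups = long_table.groupby(subject_col)[value_col]
    sizes = groups.size()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects with >= 2 visits each")
    y = long_table[value_col].to_numpy(float)
    N = len(y)
    n_subj = len(sizes)
    grand = y.mean()
    means = groups.mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((long_table[value_col] - long_table[subject_col].map(means)) ** 2).sum())
    msb = ssb / (n_subj - 1)
    dfw = N - n_subj
    msw = ssw / dfw if dfw > 0 else 0.0
    k0 = (N - float((sizes**2).sum()) / N) / (n_subj - 1)
    denom = msb + (k0 - 1.0) * msw
    if denom == 0.0:
        logger.warning("zero variance in both between- and within-subject terms; ICC undefined")
        return float("nan")
    return float((msb - msw) / denom)
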