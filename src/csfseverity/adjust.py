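"""Healthy-volunteer-anchored age and sex adjustment of the analyte panel.

The two-tier screen identifies analytes whose CSF levels carry physiological
age/sex effects:

* **Tier 1** starts from analytes flagged significant in an external serum
  reference study and requires (A) a significant HV-CSF association whose
  direction matches the serum reference, and (B) a significant (FDR-adjusted)
  association in the MS cohort.  Each selected analyte is additionally
  labelled concordant/discordant by comparing the signs of the MS and HV
  coefficients — discordance marks a candidate disease process but does not
  block adjustment.
* **Tier 2** rescues analytes absent from the reference whose HV-CSF
  association survives Bonferroni correction across that remaining family.

Adjustment subtracts the HV-estimated covariate component from every sample
(HV and MS alike) and re-anchors values at the HV mean, so adjusted values
stay on an interpretable log-RFU scale.  Analytes associated with both age
and sex are adjusted jointly from a single HV regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screen import bh_adjust

logger = logging.getLogger("csfseverity")

__all__ = ["fit_cohort_regressions", "screen_tier1", "screen_tier2",
           "build_adjustment_models", "adjust_panel", "AdjustmentModels",
           "bonferroni_adjust"]


def bonferroni_adjust(p: np.ndarray) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p.size * p)


def fit_cohort_regressions(panel: pd.DataFrame, metadata: pd.DataFrame,
                           cohort: str) -> pd.DataFrame:
    """Per-analyte OLS of log RFU on age + sex indicator within one cohort.

    Returns one row per (analyte, covariate) with the coefficient, its
    two-sided p-value, and the coefficient sign.
    """
    mask = metadata["cohort"] == cohort
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 samples in cohort {cohort!r}, got {n}")
    age = metadata.loc[mask, "age"].to_numpy(float)
    sex = metadata.loc[mask, "sex_indicator"].to_numpy(float)
    for name, v in (("age", age), ("sex", sex)):
        if np.ptp(v) == 0:
            raise ValueError(f"covariate {name!r} is constant in cohort {cohort!r}")
    Y = panel.loc[mask.index[mask]].to_numpy(float)
    X = np.column_stack([np.ones(n), age, sex])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                     # 3 x p
    resid = Y - X @ beta
    dof = n - 3
    if dof < 1:
        raise ValueError(f"not enough residual degrees of freedom in cohort {cohort!r}")
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # 3 x p
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)

    rows = []
    for j, cov in ((1, "age"), (2, "sex")):
        rows.append(pd.DataFrame({
            "analyte_id": panel.columns,
            "covariate": cov,
            "cohort": cohort,
            "coefficient": beta[j],
            "p_value": pval[j],
        }))
    out = pd.concat(rows, ignore_index=True)
    out["direction"] = np.where(out["coefficient"] >= 0, "+", "-")
    return out


def screen_tier1(reference: pd.DataFrame, hv_assoc: pd.DataFrame,
                 ms_assoc: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Reference-prioritized screen (tier 1).

    ``reference`` is restricted to its significant rows.  Selection requires
    criterion A (HV-CSF p < alpha with the serum-concordant direction) and
    criterion B (BH-adjusted MS p < alpha within the candidate family, per
    covariate).  Returns the selected rows with an ``ms_concordant_with_hv``
    flag from the MS-vs-HV coefficient sign comparison.
    """
    ref = reference[reference["significant"]].copy()
    hv = hv_assoc.set_index(["analyte_id", "covariate"])
    ms = ms_assoc.set_index(["analyte_id", "covariate"])
    selected = []
    for cov in ("age", "sex"):
        cand = ref[ref["covariate"] == cov]
        cand = cand[~cand["analyte_id"].duplicated()]
        present = []
        for aid in cand["analyte_id"]:
            if (aid, cov) not in hv.index:
                logger.warning("reference analyte %s absent from panel; skipped", aid)
                continue
            present.append(aid)
        if not present:
            continue
        cand = cand.set_index("analyte_id").loc[present]
        hv_c = hv.loc[[(a, cov) for a in present]].reset_index(level=1, drop=True)
        ms_c = ms.loc[[(a, cov) for a in present]].reset_index(level=1, drop=True)
        ms_adj = bh_adjust(ms_c["p_value"].to_numpy())
        crit_a = ((hv_c["p_value"].to_numpy() < alpha)
                  & (np.sign(hv_c["coefficient"].to_numpy())
                     == np.sign(cand["coefficient"].to_numpy())))
        crit_b = ms_adj < alpha
        keep = crit_a & crit_b
        out = pd.DataFrame({
            "analyte_id": present,
            "covariate": cov,
            "hv_coefficient": hv_c["coefficient"].to_numpy(),
            "hv_p": hv_c["p_value"].to_numpy(),
            "ms_coefficient": ms_c["coefficient"].to_numpy(),
            "ms_adjusted_p": ms_adj,
            "ms_concordant_with_hv": np.sign(ms_c["coefficient"].to_numpy())
                                     == np.sign(hv_c["coefficient"].to_numpy()),
        })[keep]
        selected.append(out)
    if not selected:
        return pd.DataFrame(columns=["analyte_id", "covariate", "hv_coefficient", "hv_p",
                                     "ms_coefficient", "ms_adjusted_p",
                                     "ms_concordant_with_hv"])
    res = pd.concat(selected, ignore_index=True)
    res["tier"] = 1
    return res


def screen_tier2(non_candidates: list, hv_assoc: pd.DataFrame,
                 family_alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni rescue of analytes outside the reference-prioritized set."""
    if len(non_candidates) == 0:
        return pd.DataFrame(columns=["analyte_id", "covariate", "hv_coefficient",
                                     "hv_p", "tier"])
    hv = hv_assoc[hv_assoc["analyte_id"].isin(non_candidates)]
    out = []
    for cov in ("age", "sex"):
        fam = hv[hv["covariate"] == cov]
        m = len(fam)
        if m == 0:
            continue
        keep = fam["p_value"].to_numpy() < family_alpha / m
        sel = fam[keep]
        out.append(pd.DataFrame({
            "analyte_id": sel["analyte_id"].to_numpy(),
            "covariate": cov,
            "hv_coefficient": sel["coefficient"].to_numpy(),
            "hv_p": sel["p_value"].to_numpy(),
        }))
    if not out:
        return pd.DataFrame(columns=["analyte_id", "covariate", "hv_coefficient",
                                     "hv_p", "tier"])
    res = pd.concat(out, ignore_index=True)
    res["tier"] = 2
    return res


@dataclass
class AdjustmentModels:
    """Per-analyte HV regressions used for adjustment.

    ``table`` has one row per adjusted analyte: the jointly fitted HV
    intercept, age slope and sex effect, which covariates to subtract, the
    HV anchor (mean age, sex-indicator mean), the tier, and the MS/HV
    concordance flag.
    """

    table: pd.DataFrame
    hv_mean_age: float
    hv_sex_baseline: float


def build_adjustment_models(panel: pd.DataFrame, metadata: pd.DataFrame,
                            tier1: pd.DataFrame, tier2: pd.DataFrame) -> AdjustmentModels:
    """Joint HV regression per selected analyte.

    An analyte selected for both age and sex is adjusted for both from a
    single joint fit, avoiding double-counting of shared variance.
    """
    hv_mask = metadata["cohort"] == "HV"
    age = metadata.loc[hv_mask, "age"].to_numpy(float)
    sex = metadata.loc[hv_mask, "sex_indicator"].to_numpy(float)
    mean_age = float(age.mean())
    sex_base = float(sex.mean())

    sel = pd.concat([tier1[["analyte_id", "covariate", "tier"]],
                     tier2[["analyte_id", "covariate", "tier"]]], ignore_index=True)
    rows = []
    X = np.column_stack([np.ones(len(age)), age, sex])
    pinv = np.linalg.pinv(X)
    for aid, grp in sel.groupby("analyte_id", sort=True):
        if aid not in panel.columns:
            raise KeyError(f"adjustment model requested for absent analyte {aid!r}")
        beta = pinv @ panel.loc[hv_mask.index[hv_mask], aid].to_numpy(float)
        covs = set(grp["covariate"])
        conc = tier1.loc[tier1["analyte_id"] == aid, "ms_concordant_with_hv"]
        rows.append({
            "analyte_id": aid,
            "adjust_age": "age" in covs,
            "adjust_sex": "sex" in covs,
            "hv_intercept": beta[0],
            "hv_age_slope": beta[1],
            "hv_sex_effect": beta[2],
            "hv_mean_age": mean_age,
            "hv_sex_baseline": sex_base,
            "tier": int(grp["tier"].min()),
            "ms_concordant_with_hv": bool(conc.all()) if len(conc) else True,
        })
    table = pd.DataFrame(rows).set_index("analyte_id") if rows else pd.DataFrame(
        columns=["adjust_age", "adjust_sex", "hv_intercept", "hv_age_slope",
                 "hv_sex_effect", "hv_mean_age", "hv_sex_baseline", "tier",
                 "ms_concordant_with_hv"])
    return AdjustmentModels(table=table, hv_mean_age=mean_age, hv_sex_baseline=sex_base)


def adjust_panel(panel: pd.DataFrame, metadata: pd.DataFrame,
                 models: AdjustmentModels) -> pd.DataFrame:
    """Subtract the HV-estimated age/sex component from every sample.

    adjusted = observed - slope_age * (age - hv_mean_age)
                        - effect_sex * (sex - hv_sex_baseline)
    for the covariates the analyte was selected for; unselected analytes pass
    through bit-identical.
    """
    absent = [a for a in models.table.index if a not in panel.columns]
    if absent:
        raise KeyError(f"adjustment models for analytes absent from panel: {absent}")
    out = panel.copy()
    age = metadata.loc[panel.index, "age"].to_numpy(float)
    sex = metadata.loc[panel.index, "sex_indicator"].to_numpy(float)
    for aid, m in models.table.iterrows():
        col = out[aid].to_numpy(float)
        if m["adjust_age"]:
            col = col - m["hv_age_slope"] * (age - m["hv_mean_age"])
        if m["adjust_sex"]:
            col = col - m["hv_sex_effect"] * (sex - m["hv_sex_baseline"])
        out[aid] = col
    return out
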