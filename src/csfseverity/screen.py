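"""Univariate severity screen: per-analyte Spearman correlations with FDR.

Every adjusted analyte is rank-correlated with each severity outcome over
the MS baseline samples; p-values are Benjamini-Hochberg adjusted within
each outcome family.  Ranked symbol lists are exported in the plain-text
formats that external enrichment services (STRING-style ordered-by-|rho|,
g:Profiler-style ordered-by-p) accept.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("csfseverity")

__all__ = ["bh_adjust", "spearman", "correlate_outcomes", "rank_for_enrichment"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1; monotone in p.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def spearman(x: np.ndarray, y: np.ndarray):
    """Spearman rho with two-sided p (Pearson on average ranks, t reference)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return float(rho), float(p)


def correlate_outcomes(adjusted_panel: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho + BH-adjusted p per analyte x outcome.

    ``outcomes`` is a sample-indexed frame of severity outcome columns;
    samples with a missing outcome are dropped per outcome.  Constant
    analytes yield NaN rho with a warning; a constant outcome is fatal.
    """
    results = []
    for out_name in outcomes.columns:
        y_all = outcomes[out_name]
        keep = y_all.notna()
        if int(keep.sum()) < 4:
            raise ValueError(f"outcome {out_name!r}: need >= 4 paired observations")
        y = y_all[keep].to_numpy(float)
        if np.ptp(y) == 0:
            raise ValueError(f"outcome {out_name!r} is constant")
        sub = adjusted_panel.loc[keep[keep].index]
        rhos = np.empty(sub.shape[1])
        ps = np.empty(sub.shape[1])
        for j, aid in enumerate(sub.columns):
            rhos[j], ps[j] = spearman(sub[aid].to_numpy(float), y)
            if np.isnan(rhos[j]):
                logger.warning("analyte %s is constant; rho undefined", aid)
        valid = ~np.isnan(ps)
        q = np.full_like(ps, np.nan)
        q[valid] = bh_adjust(ps[valid])
        df = pd.DataFrame({
            "analyte_id": sub.columns,
            "outcome": out_name,
            "spearman_rho": rhos,
            "p_value": ps,
            "fdr_q": q,
        })
        df["rank"] = df["p_value"].rank(method="first").astype("Int64")
        results.append(df)
    return pd.concat(results, ignore_index=True)


def rank_for_enrichment(screen_results: pd.DataFrame, outdir: str | Path,
                        symbol_map: dict | None = None,
                        q_threshold: float = 0.05) -> dict:
    """Write ordered symbol lists per outcome for external enrichment tools.

    For each outcome: ``by_rho`` (decreasing |rho|), ``by_p`` (increasing p),
    and the significant positive/negative sublists (fdr_q < threshold split
    by rho sign).  Unmapped analytes keep their aptamer ID with a warning.
    Returns {outcome: {kind: path}}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    symbol_map = symbol_map or {}

    def sym(aid):
        if aid not in symbol_map:
            if symbol_map:
                logger.warning("no gene symbol for analyte %s; keeping aptamer ID", aid)
            return aid
        return symbol_map[aid]

    written = {}
    for out_name, grp in screen_results.groupby("outcome", sort=True):
        grp = grp.dropna(subset=["p_value"])
        paths = {}
        orders = {
            "by_rho": grp.reindex(grp["spearman_rho"].abs()
                                  .sort_values(ascending=False, kind="stable").index),
            "by_p": grp.sort_values("p_value", kind="stable"),
        }
        sig = grp[grp["fdr_q"] < q_threshold]
        orders["pos"] = sig[sig["spearman_rho"] > 0].sort_values("p_value", kind="stable")
        orders["neg"] = sig[sig["spearman_rho"] < 0].sort_values("p_value", kind="stable")
        for kind, sub in orders.items():
            path = outdir / f"ranked_{out_name}_{kind}.txt"
            path.write_text("".join(sym(a) + "\n" for a in sub["analyte_id"]))
            paths[kind] = path
        written[out_name] = paths
    return written
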