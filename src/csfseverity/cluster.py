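"""Heterogeneity analysis: protein modules and patient clusters.

Model-selected analytes are z-scored over the MS cohort and clustered by
agglomerative hierarchical clustering with Ward minimum-variance linkage on
Euclidean distances (the convention in which input distances are squared
before the Lance-Williams update, i.e. "ward.D2").  Cutting the column tree
yields patient clusters and the row tree protein modules.  Clustering is
fully deterministic: identical input gives an identical dendrogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger("csfseverity")

__all__ = ["zscore_matrix", "cluster_bimodal", "summarize_clusters", "ClusterAssignment"]


def zscore_matrix(adjusted_panel: pd.DataFrame, selected_analytes,
                  cohort_mask: pd.Series) -> pd.DataFrame:
    """Per-analyte z-scores over the masked (MS) cohort; zero-SD analytes dropped."""
    mask = cohort_mask.astype(bool)
    if int(mask.sum()) < 2:
        raise ValueError("need >= 2 samples in the cohort mask")
    if len(selected_analytes) == 0:
        raise ValueError("selected analyte set is empty")
    sub = adjusted_panel.loc[mask[mask].index, list(selected_analytes)]
    sd = sub.std(ddof=0)
    dead = sd.index[sd == 0].tolist()
    if dead:
        logger.warning("dropping zero-variance analytes from z-matrix: %s", dead)
        sub = sub.drop(columns=dead)
        sd = sd.drop(index=dead)
    return (sub - sub.mean()) / sd


@dataclass
class ClusterAssignment:
    patient_clusters: pd.Series     # sample_id -> 1..k_patients
    protein_modules: pd.Series      # analyte_id -> 1..k_modules
    patient_linkage: np.ndarray
    module_linkage: np.ndarray
    z: pd.DataFrame


def cluster_bimodal(z: pd.DataFrame, k_patients: int = 7,
                    k_modules: int = 4) -> ClusterAssignment:
    """Ward hierarchical clustering of samples (rows of z) and analytes (columns)."""
    n, p = z.shape
    if k_patients > n:
        raise ValueError(f"k_patients={k_patients} exceeds sample count {n}")
    if k_modules > p:
        raise ValueError(f"k_modules={k_modules} exceeds analyte count {p}")
    zl = linkage(z.to_numpy(), method="ward")
    ml = linkage(z.to_numpy().T, method="ward")
    patients = pd.Series(fcluster(zl, t=k_patients, criterion="maxclust"),
                         index=z.index, name="patient_cluster")
    modules = pd.Series(fcluster(ml, t=k_modules, criterion="maxclust"),
                        index=z.columns, name="protein_module")
    return ClusterAssignment(patient_clusters=patients, protein_modules=modules,
                             patient_linkage=zl, module_linkage=ml, z=z)


def summarize_clusters(assignment: ClusterAssignment, metadata: pd.DataFrame,
                       outcomes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-patient-cluster composition: n, subtype/sex counts, median outcomes,
    mean module z per protein module."""
    meta = metadata.loc[assignment.patient_clusters.index]
    rows = []
    for cid, members in assignment.patient_clusters.groupby(assignment.patient_clusters):
        ids = members.index
        row = {"cluster": int(cid), "n": len(ids)}
        for st, cnt in meta.loc[ids, "subtype"].value_counts().items():
            row[f"n_{st}"] = int(cnt)
        for sx, cnt in meta.loc[ids, "sex"].value_counts().items():
            row[f"n_sex_{sx}"] = int(cnt)
        if outcomes is not None:
            for col in outcomes.columns:
                vals = outcomes.loc[outcomes.index.intersection(ids), col].dropna()
                if len(vals) == 0:
                    logger.warning("cluster %d: outcome %r empty; omitted", cid, col)
                    continue
                row[f"median_{col}"] = float(vals.median())
        for mid, analytes in assignment.protein_modules.groupby(assignment.protein_modules):
            row[f"mean_z_module{int(mid)}"] = float(
                assignment.z.loc[ids, analytes.index].to_numpy().mean())
        rows.append(row)
    return pd.DataFrame(rows).fillna(0).sort_values("cluster").reset_index(drop=True)
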