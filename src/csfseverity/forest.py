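"""Ratio feature expansion and importance-guided backward elimination.

The severity models treat every analyte and every pairwise analyte ratio as
a candidate feature.  On the log scale a ratio is the difference of two
analyte columns; each unordered pair appears once, oriented so the
numerator is the lexicographically smaller analyte ID.

Feature selection repeats: fit ``n_forests_per_step`` regression forests,
record the mean/SD of their out-of-bag (OOB) mean-squared errors, average
their node-impurity importances, drop the bottom ``drop_fraction`` of
features (ties broken by feature ID), and iterate until ``floor`` features
remain.  The cut point is the step minimizing the mean OOB error
(configurable to a one-standard-error rule preferring the smallest feature
count within one SD of the minimum).  The final model is a single forest
with ``ntree_final`` trees and mtry = 3*sqrt(p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rf import RegressionForest, fit_forest, presort
from .config import RFParams

logger = logging.getLogger("csfseverity")

__all__ = ["FeatureMatrix", "expand_ratios", "ratio_feature_count",
           "elimination_sequence", "iterative_selection", "SelectionResult",
           "fit_final_model", "SeverityModelBundle", "predict"]


def ratio_feature_count(p: int) -> int:
    """Feature count for p analytes: singles plus unordered pairs."""
    return p + p * (p - 1) // 2


def elimination_sequence(p: int, drop_fraction: float = 0.10, floor: int = 3) -> list:
    """Deterministic feature-count sequence p -> p - max(1, floor(frac*p)) down to floor."""
    seq = [p]
    while p > floor:
        p = max(floor, p - max(1, int(drop_fraction * p)))
        seq.append(p)
    return seq


@dataclass
class FeatureMatrix:
    """Sample x feature values with feature provenance.

    Feature IDs are either a bare analyte ID or ``A/B`` (a ratio stored as
    the log difference value(A) - value(B), A lexicographically before B).
    """

    values: np.ndarray                 # (n_samples, n_features) float64
    feature_ids: list
    sample_ids: list

    def __post_init__(self) -> None:
        self._index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def shape(self):
        return self.values.shape

    def subset(self, ids) -> "FeatureMatrix":
        missing = [f for f in ids if f not in self._index]
        if missing:
            raise KeyError(f"features absent from matrix: {missing[:5]}")
        cols = [self._index[f] for f in ids]
        return FeatureMatrix(values=np.ascontiguousarray(self.values[:, cols]),
                             feature_ids=list(ids), sample_ids=self.sample_ids)

    @staticmethod
    def analytes_of(feature_id: str) -> tuple:
        return tuple(feature_id.split("/"))

    def unique_analytes(self) -> list:
        out = set()
        for f in self.feature_ids:
            out.update(self.analytes_of(f))
        return sorted(out)


def expand_ratios(adjusted_panel: pd.DataFrame) -> FeatureMatrix:
    """Singles plus one log-difference per unordered analyte pair."""
    if adjusted_panel.columns.duplicated().any():
        raise ValueError("duplicate analyte IDs in panel")
    analytes = sorted(adjusted_panel.columns)
    X = adjusted_panel[analytes].to_numpy(float)
    n, p = X.shape
    i_idx, j_idx = np.triu_indices(p, k=1)
    values = np.empty((n, ratio_feature_count(p)))
    values[:, :p] = X
    values[:, p:] = X[:, i_idx] - X[:, j_idx]
    ids = list(analytes) + [f"{analytes[i]}/{analytes[j]}" for i, j in zip(i_idx, j_idx)]
    return FeatureMatrix(values=values, feature_ids=ids,
                         sample_ids=list(adjusted_panel.index))


def features_from_panel(adjusted_panel: pd.DataFrame, feature_ids) -> FeatureMatrix:
    """Materialize only the named single/ratio features (for new cohorts)."""
    cols = np.empty((adjusted_panel.shape[0], len(feature_ids)))
    for k, fid in enumerate(feature_ids):
        parts = fid.split("/")
        if len(parts) == 1:
            cols[:, k] = adjusted_panel[parts[0]].to_numpy(float)
        else:
            a, b = parts
            cols[:, k] = (adjusted_panel[a].to_numpy(float)
                          - adjusted_panel[b].to_numpy(float))
    return FeatureMatrix(values=cols, feature_ids=list(feature_ids),
                         sample_ids=list(adjusted_panel.index))


def _child_seed(seed: int, step: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(step), int(rep)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SelectionResult:
    trace: pd.DataFrame                # step, n_features, oob_error_mean/sd, dropped
    selected: list                     # surviving feature IDs at the cut step
    cut_step: int
    importances: pd.Series             # mean importance per feature at the cut step


def iterative_selection(features: FeatureMatrix, outcome: np.ndarray,
                        params: RFParams, seed: int) -> SelectionResult:
    """Backward elimination by averaged node-impurity importance with OOB cut."""
    y = np.asarray(outcome, dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome contains missing values")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    if len(features.feature_ids) < 4:
        raise ValueError("need at least 4 candidate features")

    current = list(features.feature_ids)
    col_index = {f: i for i, f in enumerate(features.feature_ids)}
    Xfull = features.values
    rows = []
    step_features: list = []
    step_importances: list = []
    step = 0
    while True:
        p = len(current)
        cols = np.array([col_index[f] for f in current])
        X = np.ascontiguousarray(Xfull[:, cols])
        presorted = presort(X)
        mtry = RFParams.mtry(p)
        oob = np.empty(params.n_forests_per_step)
        imp = np.zeros(p)
        for rep in range(params.n_forests_per_step):
            f = fit_forest(X, y, n_trees=params.ntree_selection, mtry=mtry,
                           seed=_child_seed(seed, step, rep),
                           min_leaf=params.min_node_size, presorted=presorted)
            oob[rep] = f.oob_mse()
            imp += f.importance
        imp /= params.n_forests_per_step

        step_features.append(list(current))
        step_importances.append(imp.copy())
        if p <= params.floor:
            dropped: list = []
        else:
            k = max(1, int(params.drop_fraction * p))
            k = min(k, p - params.floor)
            order_drop = sorted(range(p), key=lambda i: (imp[i], current[i]))
            dropped = sorted(current[i] for i in order_drop[:k])
        rows.append({"step": step, "n_features": p,
                     "oob_error_mean": float(oob.mean()),
                     "oob_error_sd": float(oob.std(ddof=1)) if len(oob) > 1 else 0.0,
                     "dropped": ";".join(dropped)})
        logger.debug("selection step %d: p=%d oob=%.4f", step, p, oob.mean())
        if p <= params.floor:
            break
        drop_set = set(dropped)
        current = [f for f in current if f not in drop_set]
        step += 1

    trace = pd.DataFrame(rows)
    means = trace["oob_error_mean"].to_numpy()
    i_min = int(np.argmin(means))
    if params.oob_rule == "1se":
        thr = means[i_min] + trace["oob_error_sd"].iloc[i_min]
        within = np.flatnonzero(means <= thr)
        cut = int(within[np.argmin(trace["n_features"].to_numpy()[within])])
    else:
        cut = i_min
    return SelectionResult(
        trace=trace,
        selected=step_features[cut],
        cut_step=cut,
        importances=pd.Series(step_importances[cut], index=step_features[cut],
                              name="importance"),
    )


@dataclass
class SeverityModelBundle:
    """A frozen severity model: selected features plus the final forest."""

    outcome_name: str
    feature_ids: list
    forest: RegressionForest
    ntree: int
    mtry: int
    seed: int
    training_oob_mse: float
    unique_analytes: list = field(default_factory=list)

    def spec(self) -> dict:
        return {"outcome": self.outcome_name, "features": self.feature_ids,
                "unique_analytes": self.unique_analytes, "ntree": self.ntree,
                "mtry": self.mtry, "seed": self.seed,
                "training_oob_mse": self.training_oob_mse}


def fit_final_model(features: FeatureMatrix, outcome: np.ndarray,
                    params: RFParams, seed: int,
                    outcome_name: str = "severity") -> SeverityModelBundle:
    """Single forest with ntree_final trees and mtry = 3*sqrt(p) on the selected set."""
    y = np.asarray(outcome, dtype=float)
    p = len(features.feature_ids)
    mtry = RFParams.mtry(p)
    forest = fit_forest(features.values, y, n_trees=params.ntree_final, mtry=mtry,
                        seed=seed, min_leaf=params.min_node_size)
    return SeverityModelBundle(
        outcome_name=outcome_name, feature_ids=list(features.feature_ids),
        forest=forest, ntree=params.ntree_final, mtry=mtry, seed=seed,
        training_oob_mse=forest.oob_mse(),
        unique_analytes=features.unique_analytes())


def predict(bundle: SeverityModelBundle, features: FeatureMatrix,
            oob: bool = False) -> np.ndarray:
    """Forest-mean predictions; ``oob=True`` returns training OOB predictions."""
    if oob:
        return bundle.forest.oob_prediction()
    sub = features.subset(bundle.feature_ids)
    return bundle.forest.predict(sub.values)
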