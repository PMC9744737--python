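"""Ratio expansion, elimination mechanics and the regression-forest engine."""

import numpy as np
import pandas as pd
import pytest

from csfseverity._rf import fit_forest
from csfseverity.config import RFParams
from csfseverity.forest import (FeatureMatrix, elimination_sequence, expand_ratios,
                                features_from_panel, fit_final_model,
                                iterative_selection, predict, ratio_feature_count)


def _panel(values, analytes, n=None):
    values = np.asarray(values, float)
    return pd.DataFrame(values, columns=analytes,
                        index=[f"S{i}" for i in range(values.shape[0])])


def test_ratio_expansion_three_analytes():
    panel = _panel([[1.0, 2.0, 4.0], [2.0, 3.0, 1.0]], ["A", "B", "C"])
    fm = expand_ratios(panel)
    assert fm.feature_ids == ["A", "B", "C", "A/B", "A/C", "B/C"]
    assert fm.shape == (2, 6)
    # log-ratio = difference; lexicographically smaller analyte is numerator
    assert fm.values[0, 3] == pytest.approx(1.0 - 2.0)
    assert fm.values[1, 5] == pytest.approx(3.0 - 1.0)


def test_ratio_antisymmetry_single_orientation(rng):
    panel = _panel(rng.standard_normal((5, 4)), ["W", "Q", "A", "M"])
    fm = expand_ratios(panel)
    ids = set(fm.feature_ids)
    for f in fm.feature_ids:
        parts = f.split("/")
        if len(parts) == 2:
            a, b = parts
            assert a < b
            assert f"{b}/{a}" not in ids
            col = fm.values[:, fm.feature_ids.index(f)]
            reversed_val = panel[b].to_numpy() - panel[a].to_numpy()
            assert np.allclose(col, -reversed_val)


def test_ratio_count_formula():
    assert ratio_feature_count(3) == 6
    assert ratio_feature_count(60) == 1830
    assert ratio_feature_count(1305) == 852_165


def test_duplicate_analytes_fatal(rng):
    panel = _panel(rng.standard_normal((3, 2)), ["A", "A"])
    with pytest.raises(ValueError, match="duplicate"):
        expand_ratios(panel)


def test_elimination_sequences_match_rule():
    assert elimination_sequence(10) == [10, 9, 8, 7, 6, 5, 4, 3]
    assert elimination_sequence(100) == [
        100, 90, 81, 73, 66, 60, 54, 49, 45, 41, 37, 34, 31, 28, 26, 24, 22,
        20, 18, 17, 16, 15, 14, 13, 12, 11, 10, 9, 8, 7, 6, 5, 4, 3]


@pytest.mark.parametrize("p,expected", [(57, 23), (1, 1), (4, 4), (1830, 128)])
def test_mtry_rule_round_half_up_clipped(p, expected):
    assert RFParams.mtry(p) == expected


def test_features_from_panel_matches_expansion(rng):
    panel = _panel(rng.standard_normal((6, 5)), list("ABCDE"))
    fm = expand_ratios(panel)
    sub = features_from_panel(panel, ["B", "A/C", "D/E"])
    full = fm.subset(["B", "A/C", "D/E"])
    assert np.allclose(sub.values, full.values)
    with pytest.raises(KeyError):
        fm.subset(["Z/Q"])


def test_forest_engine_against_sklearn_oracle(rng):
    """Independent cross-check: OOB error, importances and predictions agree
    with sklearn's RandomForestRegressor on a planted linear signal."""
    from sklearn.ensemble import RandomForestRegressor
    n, p = 120, 30
    X = rng.standard_normal((n, p))
    y = 2 * X[:, 0] - X[:, 1] + 0.5 * rng.standard_normal(n)
    mine = fit_forest(X, y, n_trees=300, mtry=10, seed=1, min_leaf=5)
    skl = RandomForestRegressor(n_estimators=300, max_features=10,
                                min_samples_leaf=5, oob_score=True, random_state=0)
    skl.fit(X, y)
    skl_oob = float(((skl.oob_prediction_ - y) ** 2).mean())
    assert mine.oob_mse() == pytest.approx(skl_oob, rel=0.15)
    skl_imp = sum(e.tree_.compute_feature_importances(normalize=False)
                  for e in skl.estimators_) / 300
    assert np.corrcoef(mine.importance, skl_imp)[0, 1] > 0.98
    assert np.corrcoef(mine.predict(X), skl.predict(X))[0, 1] > 0.98
    # the planted features dominate the importance ranking
    assert set(np.argsort(mine.importance)[-2:]) == {0, 1}


def test_forest_determinism_and_seed_sensitivity(rng):
    X = rng.standard_normal((60, 10))
    y = X[:, 0] + rng.standard_normal(60)
    a = fit_forest(X, y, n_trees=100, mtry=3, seed=5)
    b = fit_forest(X, y, n_trees=100, mtry=3, seed=5)
    c = fit_forest(X, y, n_trees=100, mtry=3, seed=6)
    assert np.array_equal(a.predict(X), b.predict(X))
    assert not np.array_equal(a.predict(X), c.predict(X))


def test_oob_fraction_matches_bootstrap_theory(rng):
    """Each sample is OOB in ~exp(-1) of the trees (bootstrap contract)."""
    X = rng.standard_normal((100, 5))
    y = rng.standard_normal(100)
    f = fit_forest(X, y, n_trees=500, mtry=2, seed=3)
    frac = f._oob_cnt.mean() / 500
    assert 0.33 < frac < 0.41


def test_monotone_transform_invariance(rng):
    """exp-transforming features preserves value order, hence identical
    trees and identical predictions (thresholds sit at observed values, so
    routing is order-isomorphic under strictly monotone transforms)."""
    X = rng.standard_normal((80, 6))
    y = X[:, 0] - X[:, 3] + 0.3 * rng.standard_normal(80)
    Xnew = rng.standard_normal((20, 6))
    a = fit_forest(X, y, n_trees=100, mtry=3, seed=9)
    b = fit_forest(np.exp(X), y, n_trees=100, mtry=3, seed=9)
    assert np.allclose(a.predict(Xnew), b.predict(np.exp(Xnew)), atol=1e-12)
    assert a.oob_mse() == pytest.approx(b.oob_mse(), abs=1e-12)
    assert np.allclose(a.importance, b.importance, atol=1e-12)


def test_near_interpolation_on_noiseless_signal(rng):
    X = rng.standard_normal((150, 8))
    y = 3 * X[:, 0] + X[:, 1]
    f = fit_forest(X, y, n_trees=500, mtry=8, seed=2, min_leaf=1)
    pred = f.predict(X)
    r2 = 1 - ((pred - y) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    assert r2 >= 0.95


def test_constant_outcome_predicts_constant(rng):
    X = rng.standard_normal((30, 4))
    y = np.full(30, 2.5)
    params = RFParams(ntree_final=50)
    fm = FeatureMatrix(values=X, feature_ids=list("ABCD"),
                       sample_ids=[f"S{i}" for i in range(30)])
    bundle = fit_final_model(fm, y, params, seed=1)
    assert np.allclose(predict(bundle, fm), 2.5, atol=1e-12)


def test_iterative_selection_trace_and_recovery(rng):
    """The count sequence follows the deterministic rule and the planted
    signal features survive to the cut."""
    n, p = 100, 20
    X = rng.standard_normal((n, p))
    y = 2 * X[:, 0] - 2 * X[:, 1] + 0.3 * rng.standard_normal(n)
    ids = [f"F{i:02d}" for i in range(p)]
    fm = FeatureMatrix(values=X, feature_ids=ids, sample_ids=[f"S{i}" for i in range(n)])
    params = RFParams(ntree_selection=100, n_forests_per_step=5)
    res = iterative_selection(fm, y, params, seed=4)
    assert res.trace["n_features"].tolist() == elimination_sequence(p)
    assert res.trace["n_features"].is_monotonic_decreasing
    assert {"F00", "F01"} <= set(res.selected)
    # determinism
    res2 = iterative_selection(fm, y, params, seed=4)
    assert res2.selected == res.selected
    assert res2.trace["oob_error_mean"].equals(res.trace["oob_error_mean"])


def test_iterative_selection_input_contracts(rng):
    fm = FeatureMatrix(values=rng.standard_normal((10, 5)),
                       feature_ids=list("ABCDE"), sample_ids=[f"S{i}" for i in range(10)])
    params = RFParams(ntree_selection=10, n_forests_per_step=2)
    with pytest.raises(ValueError, match="constant"):
        iterative_selection(fm, np.ones(10), params, seed=0)
    small = FeatureMatrix(values=rng.standard_normal((10, 3)),
                          feature_ids=list("ABC"), sample_ids=[f"S{i}" for i in range(10)])
    with pytest.raises(ValueError, match="4 candidate"):
        iterative_selection(small, rng.standard_normal(10), params, seed=0)


def test_final_model_bundle_unique_analytes(rng):
    fm = FeatureMatrix(values=rng.standard_normal((30, 3)),
                       feature_ids=["APT1", "APT2/APT3", "APT2/APT5"],
                       sample_ids=[f"S{i}" for i in range(30)])
    bundle = fit_final_model(fm, rng.standard_normal(30), RFParams(ntree_final=20), seed=0)
    assert bundle.unique_analytes == ["APT1", "APT2", "APT3", "APT5"]
    assert bundle.mtry == RFParams.mtry(3)


def test_oob_predictions_differ_from_full_forest(rng):
    """OOB mode must not let a sample's own trees vote for it: on noise data
    the OOB error is clearly larger than the in-bag (overfit) error."""
    X = rng.standard_normal((100, 10))
    y = rng.standard_normal(100)
    f = fit_forest(X, y, n_trees=300, mtry=3, seed=7, min_leaf=1)
    in_bag_mse = ((f.predict(X) - y) ** 2).mean()
    assert f.oob_mse() > 2 * in_bag_mse
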