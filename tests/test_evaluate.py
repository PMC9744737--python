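"""Evaluation statistics: CCC, prediction metrics, cohort balance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfseverity.evaluate import (compare_cohorts, concordance_ccc,
                                  evaluate_predictions, validate_progression)


def _ccc_brute(x, y):
    """Independent implementation from raw sums (population moments)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx = sum((v - mx) ** 2 for v in x) / n
    sy = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx + sy + (mx - my) ** 2)


def test_ccc_closed_forms():
    assert concordance_ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert concordance_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7, abs=1e-12)
    x = np.array([1.0, 2.0, 5.0])
    assert concordance_ccc(x, -x + 2 * x.mean()) == pytest.approx(-1.0, abs=1e-12)


@given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=2, max_size=40),
       st.integers(0, 10_000))
@settings(deadline=None, max_examples=60)
def test_ccc_matches_brute_force_and_is_bounded_by_pearson(xs, seed):
    rng = np.random.default_rng(seed)
    x = np.array(xs)
    y = x * rng.uniform(0.5, 2) + rng.standard_normal(len(x))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    ccc = concordance_ccc(x, y)
    assert ccc == pytest.approx(_ccc_brute(x, y), abs=1e-12)
    r = np.corrcoef(x, y)[0, 1]
    assert abs(ccc) <= abs(r) + 1e-12


def test_ccc_constant_input_nan():
    assert np.isnan(concordance_ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


def test_evaluate_predictions_perfect_shifted_and_reversed(rng):
    x = rng.standard_normal(50)
    perfect = evaluate_predictions(x, x)
    assert perfect["spearman_rho"] == pytest.approx(1.0)
    assert perfect["r_squared"] == pytest.approx(1.0)
    assert perfect["ccc"] == pytest.approx(1.0)
    shifted = evaluate_predictions(x, x + 1.0)
    s2 = x.var()
    assert shifted["r_squared"] == pytest.approx(1.0, abs=1e-12)
    assert shifted["ccc"] == pytest.approx(2 * s2 / (2 * s2 + 1.0), abs=1e-12)
    reversed_ranks = evaluate_predictions(x, -x)
    assert reversed_ranks["spearman_rho"] == pytest.approx(-1.0)
    # symmetry in rho/R2/ccc under swapping observed and predicted
    y = x + rng.standard_normal(50)
    a = evaluate_predictions(x, y)
    b = evaluate_predictions(y, x)
    for key in ("spearman_rho", "r_squared", "ccc"):
        assert a[key] == pytest.approx(b[key], abs=1e-12)


def test_evaluate_predictions_rejects_nans():
    with pytest.raises(ValueError):
        evaluate_predictions([1.0, np.nan, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])


def test_cohort_balance_chi_square_matches_reported_convention():
    """Sex counts 69F/60M vs 54F/44M give the continuity-corrected p ~ 0.915."""
    train = pd.DataFrame({"sex": ["F"] * 69 + ["M"] * 60, "age": 40.0})
    valid = pd.DataFrame({"sex": ["F"] * 54 + ["M"] * 44, "age": 41.0})
    table = compare_cohorts(train, valid, quantitative=()).set_index("variable")
    assert table.loc["sex", "p_value"] == pytest.approx(0.915, abs=0.005)


def test_cohort_balance_identical_and_imbalanced(rng):
    meta = pd.DataFrame({"sex": ["F"] * 30 + ["M"] * 30,
                         "age": rng.uniform(20, 70, 60)})
    same = compare_cohorts(meta, meta.copy()).set_index("variable")
    assert same.loc["sex", "p_value"] == pytest.approx(1.0)
    assert same.loc["age", "p_value"] == pytest.approx(1.0, abs=0.01)
    skew_a = pd.DataFrame({"sex": ["F"] * 90 + ["M"] * 10, "age": 40.0})
    skew_b = pd.DataFrame({"sex": ["F"] * 10 + ["M"] * 90, "age": 40.0})
    assert compare_cohorts(skew_a, skew_b, quantitative=()).set_index(
        "variable").loc["sex", "p_value"] < 1e-10


def test_progression_validation_orders_signal_above_noise(rng):
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        n = 98
        latent = rng.standard_normal(n)
        slopes = pd.Series(latent + rng.standard_normal(n),
                           index=[f"S{i}" for i in range(n)])
        predictors = pd.DataFrame({
            "model": latent + 0.8 * rng.standard_normal(n),
            "noise": rng.standard_normal(n),
        }, index=slopes.index)
        table = validate_progression(predictors, slopes).set_index("predictor")
        if table.loc["model", "spearman_rho"] > table.loc["noise", "spearman_rho"]:
            hits += 1
    assert hits >= int(0.9 * n_rep)


def test_progression_validation_duplicate_predictors_identical(rng):
    n = 40
    slopes = pd.Series(rng.standard_normal(n), index=[f"S{i}" for i in range(n)])
    x = rng.standard_normal(n)
    predictors = pd.DataFrame({"a": x, "b": x}, index=slopes.index)
    table = validate_progression(predictors, slopes).set_index("predictor")
    assert table.loc["a", "spearman_rho"] == table.loc["b", "spearman_rho"]


def test_progression_validation_skips_sparse_predictors(rng):
    n = 40
    slopes = pd.Series(rng.standard_normal(n), index=[f"S{i}" for i in range(n)])
    sparse = pd.Series(np.nan, index=slopes.index)
    sparse.iloc[:3] = 1.0
    predictors = pd.DataFrame({"ok": rng.standard_normal(n), "sparse": sparse})
    table = validate_progression(predictors, slopes)
    assert table["predictor"].tolist() == ["ok"]
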