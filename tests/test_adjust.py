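"""Two-tier age/sex screen and HV-anchored adjustment."""

import numpy as np
import pandas as pd
import pytest

from csfseverity.adjust import (AdjustmentModels, adjust_panel, bonferroni_adjust,
                                build_adjustment_models, fit_cohort_regressions,
                                screen_tier1, screen_tier2)
from csfseverity.config import PipelineConfig
from csfseverity.pipeline import stage_adjust
from csfseverity.simulate import SimulationConfig, generate_cohort


def _meta(n, ages, sexes, cohort="HV"):
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "cohort": cohort, "age": ages,
        "sex_indicator": sexes,
    }).set_index("sample_id", drop=False)


def test_ols_recovers_planted_age_and_sex_coefficients(rng):
    n = 200
    ages = rng.uniform(20, 70, n)
    sexes = rng.integers(0, 2, n).astype(float)
    meta = _meta(n, ages, sexes)
    panel = pd.DataFrame({
        "AGE": 0.02 * ages + 1e-9 * rng.standard_normal(n),
        "SEX": 1.0 * sexes + 1e-9 * rng.standard_normal(n),
    }, index=meta.index)
    assoc = fit_cohort_regressions(panel, meta, "HV").set_index(
        ["analyte_id", "covariate"])
    assert assoc.loc[("AGE", "age"), "coefficient"] == pytest.approx(0.02, abs=1e-6)
    assert abs(assoc.loc[("AGE", "sex"), "coefficient"]) < 1e-6
    assert assoc.loc[("SEX", "sex"), "coefficient"] == pytest.approx(1.0, abs=1e-6)
    assert assoc.loc[("SEX", "sex"), "direction"] == "+"


def test_null_age_pvalues_are_uniform(rng):
    """p-values of a pure-noise analyte follow Uniform(0,1)."""
    from scipy import stats
    n = 24
    pvals = []
    for _ in range(400):
        ages = rng.uniform(20, 70, n)
        sexes = rng.integers(0, 2, n).astype(float)
        meta = _meta(n, ages, sexes)
        panel = pd.DataFrame({"X": rng.standard_normal(n)}, index=meta.index)
        assoc = fit_cohort_regressions(panel, meta, "HV")
        pvals.append(assoc.set_index("covariate").loc["age", "p_value"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_constant_covariate_is_fatal(rng):
    meta = _meta(10, np.full(10, 50.0), rng.integers(0, 2, 10))
    panel = pd.DataFrame({"X": rng.standard_normal(10)}, index=meta.index)
    with pytest.raises(ValueError, match="age"):
        fit_cohort_regressions(panel, meta, "HV")


def _assoc(rows):
    return pd.DataFrame(rows, columns=["analyte_id", "covariate", "cohort",
                                       "coefficient", "p_value", "direction"])


def test_tier1_selection_rules():
    reference = pd.DataFrame({
        "analyte_id": ["A", "B", "C"], "covariate": "age",
        "coefficient": [0.01, 0.01, 0.01], "significant": True})
    hv = _assoc([("A", "age", "HV", 0.02, 0.001, "+"),
                 ("B", "age", "HV", -0.02, 0.001, "-"),
                 ("C", "age", "HV", 0.02, 0.01, "+")])
    ms = _assoc([("A", "age", "MS", 0.03, 0.001, "+"),
                 ("B", "age", "MS", 0.03, 0.001, "+"),
                 ("C", "age", "MS", -0.02, 0.001, "-")])
    sel = screen_tier1(reference, hv, ms, alpha=0.05).set_index("analyte_id")
    # A: reference "+", HV "+" significant, MS significant -> selected concordant
    assert sel.loc["A", "ms_concordant_with_hv"]
    # B: HV direction contradicts the serum reference -> rejected
    assert "B" not in sel.index
    # C: selected but MS slope sign flips vs HV -> flagged discordant
    assert not sel.loc["C", "ms_concordant_with_hv"]


def test_tier1_skips_reference_analytes_absent_from_panel(caplog):
    reference = pd.DataFrame({"analyte_id": ["Z"], "covariate": ["age"],
                              "coefficient": [0.01], "significant": [True]})
    hv = _assoc([("A", "age", "HV", 0.02, 0.001, "+")])
    ms = _assoc([("A", "age", "MS", 0.02, 0.001, "+")])
    sel = screen_tier1(reference, hv, ms)
    assert len(sel) == 0


def test_tier2_equals_bonferroni_threshold(rng):
    m = 1000
    ids = [f"N{i:04d}" for i in range(m)]
    pvals = rng.uniform(0, 1, m)
    pvals[0] = 1e-6   # selected: 1e-6 < 5e-5
    pvals[1] = 1e-4   # rejected
    hv = _assoc([(ids[i], "age", "HV", 0.01, pvals[i], "+") for i in range(m)])
    sel = screen_tier2(ids, hv, family_alpha=0.05)
    got = set(sel["analyte_id"])
    expected = {ids[i] for i in range(m) if bonferroni_adjust(pvals)[i] < 0.05}
    assert got == expected
    assert ids[0] in got and ids[1] not in got


def test_adjustment_rule_arithmetic():
    """age-only model: value 7.0, slope 0.02, mean age 40, subject age 60 -> 6.6"""
    table = pd.DataFrame([{
        "analyte_id": "A", "adjust_age": True, "adjust_sex": False,
        "hv_intercept": 0.0, "hv_age_slope": 0.02, "hv_sex_effect": 0.0,
        "hv_mean_age": 40.0, "hv_sex_baseline": 0.5, "tier": 1,
        "ms_concordant_with_hv": True}]).set_index("analyte_id")
    models = AdjustmentModels(table=table, hv_mean_age=40.0, hv_sex_baseline=0.5)
    panel = pd.DataFrame({"A": [7.0, 7.0], "B": [5.0, 5.0]},
                         index=pd.Index(["S0", "S1"], name="sample_id"))
    meta = _meta(2, [60.0, 40.0], [0, 0])
    out = adjust_panel(panel, meta, models)
    assert out.loc["S0", "A"] == pytest.approx(6.6, abs=1e-12)
    # subject at the HV anchor is unchanged; unselected analyte bit-identical
    assert out.loc["S1", "A"] == pytest.approx(7.0, abs=1e-12)
    assert (out["B"].to_numpy() == panel["B"].to_numpy()).all()


def test_adjust_panel_missing_analyte_is_fatal():
    table = pd.DataFrame([{
        "analyte_id": "Z", "adjust_age": True, "adjust_sex": False,
        "hv_intercept": 0.0, "hv_age_slope": 0.02, "hv_sex_effect": 0.0,
        "hv_mean_age": 40.0, "hv_sex_baseline": 0.5, "tier": 1,
        "ms_concordant_with_hv": True}]).set_index("analyte_id")
    models = AdjustmentModels(table=table, hv_mean_age=40.0, hv_sex_baseline=0.5)
    panel = pd.DataFrame({"A": [7.0]}, index=pd.Index(["S0"], name="sample_id"))
    with pytest.raises(KeyError, match="Z"):
        adjust_panel(panel, _meta(1, [50.0], [0]), models)


def test_adjustment_zeroes_hv_slopes_and_is_idempotent():
    cfg = SimulationConfig(seed=2, resid_sd=1e-10, module_resid_sd=1e-10)
    panel, meta, reference, truth = generate_cohort(cfg)
    pcfg = PipelineConfig()
    _, adjusted, models = stage_adjust(panel, meta, reference, pcfg)
    hv_after = fit_cohort_regressions(adjusted, meta, "HV")
    sel = models.table
    for aid, row in sel.iterrows():
        rec = hv_after.set_index(["analyte_id", "covariate"])
        if row["adjust_age"]:
            assert abs(rec.loc[(aid, "age"), "coefficient"]) < 1e-8
        if row["adjust_sex"]:
            assert abs(rec.loc[(aid, "sex"), "coefficient"]) < 1e-8
    # unselected analytes pass through bit-identical
    untouched = [a for a in panel.columns if a not in sel.index]
    assert (adjusted[untouched].to_numpy() == panel[untouched].to_numpy()).all()
    # re-adjustment with refitted models is the identity
    hv2 = fit_cohort_regressions(adjusted, meta, "HV")
    ms2 = fit_cohort_regressions(adjusted, meta, "MS")
    models2 = build_adjustment_models(
        adjusted, meta,
        screen_tier1(reference, hv2, ms2), screen_tier2(
            [a for a in panel.columns
             if a not in set(reference.loc[reference.significant, "analyte_id"])],
            hv2))
    readjusted = adjust_panel(adjusted, meta, models2)
    assert np.allclose(readjusted.to_numpy(), adjusted.to_numpy(), atol=1e-8)


def test_ms_excess_slope_survives_adjustment():
    """The disease-related age slope beyond healthy aging stays detectable."""
    cfg = SimulationConfig(seed=8)
    panel, meta, reference, truth = generate_cohort(cfg)
    _, adjusted, models = stage_adjust(panel, meta, reference, PipelineConfig())
    excess = truth.analytes.index[truth.analytes["category"] == "age_ms_excess"]
    ms_after = fit_cohort_regressions(adjusted, meta, "MS").set_index(
        ["analyte_id", "covariate"])
    for aid in excess:
        assert aid in models.table.index  # was selected and adjusted
        assert ms_after.loc[(aid, "age"), "p_value"] < 0.01
        assert ms_after.loc[(aid, "age"), "coefficient"] > 0


def test_bonferroni_rejects_out_of_range():
    with pytest.raises(ValueError):
        bonferroni_adjust(np.array([0.5, 1.2]))
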