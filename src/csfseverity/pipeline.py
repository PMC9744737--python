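"""Stage orchestration: wire the analysis modules into an end-to-end run.

Each ``stage_*`` function is a thin composition of the library modules and
returns plain DataFrames/dicts keyed by output-file stem, so the CLI can
write any stage's results as a bundle.  ``run_all`` chains every stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import adjust as adj
from . import cluster as clu
from . import clock as clk
from . import evaluate as ev
from . import forest as rf
from . import outcomes as oc
from . import screen as sc
from .config import PipelineConfig, child_seed
from .io import write_results_bundle

logger = logging.getLogger("csfseverity")

__all__ = ["stage_adjust", "stage_clock", "stage_outcomes", "stage_screen",
           "stage_train", "stage_evaluate", "stage_cluster", "run_all",
           "train_validation_split"]

SEVERITY_OUTCOMES = ["msdss_baseline", "msdss_followup", "bvd_severity"]


def stage_adjust(panel, metadata, reference, cfg: PipelineConfig):
    hv = adj.fit_cohort_regressions(panel, metadata, "HV")
    ms = adj.fit_cohort_regressions(panel, metadata, "MS")
    tier1 = adj.screen_tier1(reference, hv, ms, alpha=cfg.tier1_alpha)
    candidates = set(reference.loc[reference["significant"], "analyte_id"])
    non_candidates = [a for a in panel.columns if a not in candidates]
    tier2 = adj.screen_tier2(non_candidates, hv, family_alpha=cfg.tier2_family_alpha)
    models = adj.build_adjustment_models(panel, metadata, tier1, tier2)
    adjusted = adj.adjust_panel(panel, metadata, models)
    associations = pd.concat([hv, ms], ignore_index=True)
    return {"associations": associations, "adjustment_models": models.table.reset_index(),
            "adjusted_panel": adjusted.reset_index()}, adjusted, models


def stage_clock(panel, metadata, cfg: PipelineConfig):
    hv_mask = metadata["cohort"] == "HV"
    model = clk.train_clock(panel.loc[hv_mask[hv_mask].index], metadata.loc[hv_mask, "age"])
    predicted = clk.predict_age(model, panel)
    groups = metadata["subtype"].where(metadata["cohort"] == "MS", "HV")
    contrasts = clk.compare_delta_age(predicted, metadata["age"], groups)
    coeffs = pd.DataFrame({"analyte_id": model.analyte_ids,
                           "coefficient": model.coefficients})
    pred_df = pd.DataFrame({"sample_id": predicted.index, "predicted_age": predicted.values,
                            "observed_age": metadata.loc[predicted.index, "age"].values})
    return {"clock_coefficients": coeffs, "predicted_age": pred_df,
            "delta_age_contrasts": contrasts}, model, predicted


def stage_outcomes(metadata, cfg: PipelineConfig, long_table: pd.DataFrame | None = None):
    ms_baseline = (metadata["cohort"] == "MS") & (metadata["visit_index"] == 0)
    bvd = oc.compute_bvd_severity(metadata["bpfr"], metadata["age"], ms_baseline)
    outcomes = metadata.loc[ms_baseline, ["msdss_baseline", "msdss_followup"]].copy()
    outcomes["bvd_severity"] = bvd.residuals
    icc = {}
    if long_table is not None:
        icc["icc"] = oc.compute_icc(long_table)
    icc.update({"bvd_age_slope": bvd.slope, "bvd_age_t": bvd.t_statistic,
                "bvd_age_p": bvd.p_value})
    return {"outcomes": outcomes.reset_index(), "icc": icc}, outcomes


def stage_screen(adjusted, outcomes, cfg: PipelineConfig, outdir=None,
                 symbol_map: dict | None = None):
    res = sc.correlate_outcomes(adjusted.loc[outcomes.index], outcomes)
    bundle = {f"screen_{name}": grp.drop(columns="outcome")
              for name, grp in res.groupby("outcome")}
    if outdir is not None:
        sc.rank_for_enrichment(res, outdir, symbol_map=symbol_map)
    return bundle, res


def train_validation_split(metadata, cfg: PipelineConfig):
    """Train/validation MS sample IDs: metadata ``split`` labels if present,
    otherwise a seeded random split of sizes n_train/n_valid."""
    ms = metadata.index[(metadata["cohort"] == "MS") & (metadata["visit_index"] == 0)]
    if "split" in metadata.columns:
        train = [s for s in ms if metadata.loc[s, "split"] == "train"]
        valid = [s for s in ms if metadata.loc[s, "split"] == "valid"]
        return train, valid
    rng = np.random.default_rng(child_seed(cfg.seed, "split"))
    perm = rng.permutation(len(ms))
    n_train = min(cfg.n_train, len(ms))
    train = [ms[i] for i in sorted(perm[:n_train])]
    valid = [ms[i] for i in sorted(perm[n_train:n_train + cfg.n_valid])]
    return train, valid


def stage_train(adjusted, metadata, outcomes, cfg: PipelineConfig,
                outcome_names=None):
    train_ids, _ = train_validation_split(metadata, cfg)
    features = rf.expand_ratios(adjusted.loc[train_ids])
    bundle = {}
    models = {}
    for i, name in enumerate(outcome_names or SEVERITY_OUTCOMES):
        if name not in outcomes.columns:
            continue
        y = outcomes.loc[train_ids, name]
        if y.isna().any():
            logger.warning("outcome %s: missing training values; skipped", name)
            continue
        seed = child_seed(cfg.seed, "train", i)
        sel = rf.iterative_selection(features, y.to_numpy(), cfg.rf, seed)
        final = rf.fit_final_model(features.subset(sel.selected), y.to_numpy(),
                                   cfg.rf, child_seed(cfg.seed, "train", 100 + i),
                                   outcome_name=name)
        models[name] = final
        bundle[f"selection_trace_{name}"] = sel.trace
        bundle[f"selected_features_{name}"] = sel.importances.rename_axis(
            "feature_id").reset_index()
        bundle[f"model_{name}"] = final.spec()
    return bundle, models


def stage_evaluate(models, adjusted, metadata, outcomes, cfg: PipelineConfig):
    train_ids, valid_ids = train_validation_split(metadata, cfg)
    reports = []
    predictions = []
    pred_by_model = {}
    for name, model in models.items():
        feats_train = rf.features_from_panel(adjusted.loc[train_ids], model.feature_ids)
        feats_valid = rf.features_from_panel(adjusted.loc[valid_ids], model.feature_ids)
        pred_tr = rf.predict(model, feats_train)
        pred_va = rf.predict(model, feats_valid)
        reports.append(ev.evaluate_predictions(outcomes.loc[train_ids, name], pred_tr,
                                               outcome_name=name, cohort="training"))
        reports.append(ev.evaluate_predictions(outcomes.loc[valid_ids, name], pred_va,
                                               outcome_name=name, cohort="validation"))
        pred_by_model[f"model_{name}"] = pd.Series(pred_va, index=valid_ids)
        predictions.append(pd.DataFrame({
            "sample_id": list(train_ids) + list(valid_ids),
            "cohort": ["training"] * len(train_ids) + ["validation"] * len(valid_ids),
            "outcome": name,
            "observed": outcomes.loc[list(train_ids) + list(valid_ids), name].values,
            "predicted": np.concatenate([pred_tr, pred_va]),
        }))
    bundle = {"evaluation": reports}
    if predictions:
        bundle["predictions"] = pd.concat(predictions, ignore_index=True)
    if "progression_slope" in metadata.columns and pred_by_model:
        predictors = pd.DataFrame(pred_by_model)
        for extra in ("msdss_baseline", "armss", "msss", "snfl", "cnfl"):
            if extra in metadata.columns:
                predictors[extra] = metadata.loc[predictors.index, extra]
        prog = ev.validate_progression(predictors, metadata.loc[predictors.index,
                                                                "progression_slope"])
        bundle["progression_validation"] = prog
    balance = ev.compare_cohorts(metadata.loc[train_ids], metadata.loc[valid_ids])
    bundle["cohort_balance"] = balance
    return bundle


def stage_cluster(adjusted, metadata, models, outcomes, cfg: PipelineConfig):
    selected = sorted(set().union(*(m.unique_analytes for m in models.values())))
    ms_mask = metadata["cohort"] == "MS"
    z = clu.zscore_matrix(adjusted, selected, ms_mask)
    assignment = clu.cluster_bimodal(z, k_patients=min(cfg.k_patients, z.shape[0]),
                                     k_modules=min(cfg.k_modules, z.shape[1]))
    summary = clu.summarize_clusters(assignment, metadata, outcomes)
    return {"patient_clusters": assignment.patient_clusters.rename_axis("sample_id").reset_index(),
            "protein_modules": assignment.protein_modules.rename_axis("analyte_id").reset_index(),
            "cluster_summary": summary}, assignment


def run_all(panel, metadata, reference, cfg: PipelineConfig,
            long_table: pd.DataFrame | None = None, outdir=None):
    """Run every stage; returns the combined results dict (and writes a bundle
    when ``outdir`` is given)."""
    results = {}
    adj_bundle, adjusted, _ = stage_adjust(panel, metadata, reference, cfg)
    results.update(adj_bundle)
    clock_bundle, _, _ = stage_clock(panel, metadata, cfg)
    results.update(clock_bundle)
    out_bundle, outcomes = stage_outcomes(metadata, cfg, long_table=long_table)
    results.update(out_bundle)
    screen_bundle, _ = stage_screen(adjusted, outcomes, cfg, outdir=outdir)
    results.update(screen_bundle)
    train_bundle, models = stage_train(adjusted, metadata, outcomes, cfg)
    results.update(train_bundle)
    if models:
        results.update(stage_evaluate(models, adjusted, metadata, outcomes, cfg))
        cluster_bundle, _ = stage_cluster(adjusted, metadata, models, outcomes, cfg)
        results.update(cluster_bundle)
    if outdir is not None:
        write_results_bundle(results, outdir, config=cfg, seed=cfg.seed)
    return results
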