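"""Synthetic CSF cohorts with planted ground truth.

The generator emulates the structure of an aptamer-proteomics severity study:

* a small healthy-volunteer (HV) anchor cohort and a larger MS cohort split
  into RRMS/SPMS/PPMS subtypes with subtype-shifted age distributions;
* per-analyte log-linear age effects that are either concordant between HV
  and MS or discordant (negative in HV, positive in MS — the signature of a
  disease process masquerading as aging);
* sex shifts on a disjoint analyte set;
* disjoint severity-driving protein modules: module members share a latent
  per-sample module factor, and the latent severity is a weighted sum of the
  module analyte values plus noise;
* brain volume deficit (1 - BPFr) with a positive linear age trend plus a
  per-subject deficit that is partially coupled to severity;
* longitudinal severity with subject random intercepts, giving a
  configurable population intraclass correlation.

Every planted quantity is recorded in :class:`SyntheticTruth` so downstream
stages can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SyntheticTruth", "generate_cohort",
           "generate_longitudinal_severity", "generate_brain_volume",
           "validation_config"]


@dataclass
class SimulationConfig:
    # cohort sizes (training-like defaults; see validation_config())
    n_hv: int = 24
    n_rrms: int = 37
    n_spms: int = 31
    n_ppms: int = 61
    n_analytes: int = 60

    # analyte category counts (disjoint, assigned in order along the panel)
    n_age_concordant: int = 10
    n_age_discordant: int = 4
    n_age_tier2: int = 2          # age-associated but absent from the serum reference
    n_ms_excess: int = 1          # concordant analytes with an extra MS-only age slope
    n_sex: int = 6
    n_reference_only: int = 5     # flagged in the serum reference, null in CSF
    module_sizes: tuple = (2, 2, 1, 1)
    module_weights: tuple = (1.0, -1.0, 0.8, -0.8)

    # effect sizes
    age_slope: float = 0.02            # log-RFU per year (HV physiological effect)
    tier2_age_slope: float = 0.04      # strong enough to survive Bonferroni at n_hv=24
    ms_excess_slope: float = 0.02      # additional MS-only slope on excess analytes
    sex_shift: float = 0.5             # log-RFU female - male contrast
    resid_sd: float = 0.3              # residual SD of age/sex/noise analytes
    module_loading: float = 1.0        # loading of the module factor on member analytes
    module_resid_sd: float = 0.7       # member-specific residual SD
    severity_noise_sd: float = 4.0     # calibrated so the best single-marker rho ~ 0.35
    baseline_mean: float = 8.0         # mean log-RFU baseline (exp ~ 3000 RFU)
    baseline_sd: float = 1.0

    # ages
    hv_age_range: tuple = (20.0, 70.0)
    subtype_age: dict = field(default_factory=lambda: {
        "RRMS": (40.9, 11.1), "SPMS": (52.3, 9.0), "PPMS": (54.8, 7.9)})
    age_clip: tuple = (18.0, 75.0)
    p_female: float = 0.5

    # brain volume deficit: 1 - BPFr = a + b*age + deficit_i + noise
    bpfr_intercept: float = 0.05
    bpfr_age_slope: float = 0.002
    deficit_sd: float = 0.02
    bpfr_noise_sd: float = 0.005
    deficit_severity_corr: float = 0.5

    # longitudinal severity variance components
    k_visits: int = 5
    sigma_between_sq: float = 9.0
    sigma_within_sq: float = 1.0
    severity_mu: float = 2.0

    # secondary outcomes
    followup_noise_sd: float = 1.0
    slope_noise_sd: float = 5.0

    seed: int = 0
    # analyte-level parameters (baselines) are drawn from their own seed so a
    # validation cohort shares the measurement model of its training cohort
    analyte_seed: int | None = None

    @property
    def n_ms(self) -> int:
        return self.n_rrms + self.n_spms + self.n_ppms

    @property
    def n_module(self) -> int:
        return int(sum(self.module_sizes))

    def validate(self) -> None:
        declared = (self.n_age_concordant + self.n_age_discordant + self.n_age_tier2
                    + self.n_sex + self.n_reference_only + self.n_module)
        if declared > self.n_analytes:
            raise ValueError(
                f"declared analyte categories ({declared}) exceed n_analytes ({self.n_analytes})")
        if self.n_ms_excess > self.n_age_concordant:
            raise ValueError("n_ms_excess cannot exceed n_age_concordant")
        if len(self.module_sizes) != len(self.module_weights):
            raise ValueError("module_sizes and module_weights must have equal length")
        if min(self.n_hv, self.n_rrms, self.n_spms, self.n_ppms) < 2:
            raise ValueError("each group needs n >= 2")
        for name in ("sigma_between_sq", "sigma_within_sq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def validation_config(cfg: SimulationConfig, seed: int | None = None) -> SimulationConfig:
    """Validation-cohort variant: same planted analyte model, new subjects."""
    return replace(cfg, n_rrms=33, n_spms=24, n_ppms=41,
                   seed=cfg.seed + 1 if seed is None else seed,
                   analyte_seed=cfg.analyte_seed if cfg.analyte_seed is not None
                   else cfg.seed)


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-analyte effects and per-sample latents."""

    analytes: pd.DataFrame   # hv_age_slope, ms_age_slope, sex_effect, module_id, ...
    samples: pd.DataFrame    # latent_severity, true_deficit
    config: SimulationConfig

    @property
    def severity_analytes(self) -> list:
        m = self.analytes["severity_weight"] != 0.0
        return self.analytes.index[m].tolist()


def _analyte_truth(cfg: SimulationConfig) -> pd.DataFrame:
    ids = [f"APT{i:04d}" for i in range(cfg.n_analytes)]
    t = pd.DataFrame(index=pd.Index(ids, name="analyte_id"))
    t["hv_age_slope"] = 0.0
    t["ms_age_slope"] = 0.0
    t["sex_effect"] = 0.0
    t["module_id"] = 0
    t["severity_weight"] = 0.0
    t["in_reference"] = False
    t["category"] = "noise"

    pos = 0

    def take(n):
        nonlocal pos
        sl = slice(pos, pos + n)
        pos += n
        return t.index[sl]

    conc = take(cfg.n_age_concordant)
    t.loc[conc, "hv_age_slope"] = cfg.age_slope
    t.loc[conc, "ms_age_slope"] = cfg.age_slope
    t.loc[conc, "in_reference"] = True
    t.loc[conc, "category"] = "age_concordant"
    excess = conc[: cfg.n_ms_excess]
    t.loc[excess, "ms_age_slope"] = cfg.age_slope + cfg.ms_excess_slope
    t.loc[excess, "category"] = "age_ms_excess"

    disc = take(cfg.n_age_discordant)
    t.loc[disc, "hv_age_slope"] = -cfg.age_slope
    t.loc[disc, "ms_age_slope"] = cfg.age_slope
    t.loc[disc, "in_reference"] = True
    t.loc[disc, "category"] = "age_discordant"

    tier2 = take(cfg.n_age_tier2)
    t.loc[tier2, "hv_age_slope"] = cfg.tier2_age_slope
    t.loc[tier2, "ms_age_slope"] = cfg.tier2_age_slope
    t.loc[tier2, "category"] = "age_tier2"

    sexed = take(cfg.n_sex)
    t.loc[sexed, "sex_effect"] = cfg.sex_shift
    t.loc[sexed, "in_reference"] = True
    t.loc[sexed, "category"] = "sex"

    refonly = take(cfg.n_reference_only)
    t.loc[refonly, "in_reference"] = True
    t.loc[refonly, "category"] = "reference_only"

    for k, (size, w) in enumerate(zip(cfg.module_sizes, cfg.module_weights), start=1):
        members = take(size)
        t.loc[members, "module_id"] = k
        t.loc[members, "severity_weight"] = w
        t.loc[members, "category"] = "module"
    return t


def _reference_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Serum reference rows: significant entries mirror the planted HV signs."""
    rows = []
    for aid, row in truth.iterrows():
        if not row["in_reference"]:
            continue
        if row["sex_effect"] != 0.0:
            cov, coef = "sex", np.sign(row["sex_effect"]) * 0.3
        elif row["hv_age_slope"] != 0.0:
            cov, coef = "age", np.sign(row["hv_age_slope"]) * 0.01
        else:  # reference-only analytes claim a (spurious) positive age effect
            cov, coef = "age", 0.01
        rows.append((aid, cov, coef, True))
    # a few explicitly non-significant serum rows (ignored by the screen)
    for aid in truth.index[truth["category"] == "noise"][:3]:
        rows.append((aid, "age", 0.001, False))
    return pd.DataFrame(rows, columns=["analyte_id", "covariate", "coefficient", "significant"])


def generate_brain_volume(ages: np.ndarray, cfg: SimulationConfig,
                          rng: np.random.Generator,
                          severity_z: np.ndarray | None = None):
    """Brain parenchymal fraction with a linear age trend plus subject deficits.

    Returns ``(bpfr, true_deficit)``.  The deficit is correlated with the
    standardized latent severity at ``deficit_severity_corr`` when provided.
    """
    n = len(ages)
    z = rng.standard_normal(n)
    if severity_z is not None and cfg.deficit_severity_corr != 0.0:
        r = cfg.deficit_severity_corr
        z = r * severity_z + np.sqrt(1.0 - r**2) * z
    deficit = cfg.deficit_sd * z
    bvd = (cfg.bpfr_intercept + cfg.bpfr_age_slope * ages + deficit
           + cfg.bpfr_noise_sd * rng.standard_normal(n))
    return 1.0 - bvd, deficit


def generate_cohort(cfg: SimulationConfig):
    """Generate one cohort.

    Returns ``(panel, metadata, reference, truth)`` where the panel holds
    natural-log RFU values (samples x analytes).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth_a = _analyte_truth(cfg)
    p = cfg.n_analytes

    # subjects
    hv_ids = [f"HV{i:03d}" for i in range(cfg.n_hv)]
    ms_ids = [f"MS{i:03d}" for i in range(cfg.n_ms)]
    subtypes = (["RRMS"] * cfg.n_rrms + ["SPMS"] * cfg.n_spms + ["PPMS"] * cfg.n_ppms)
    ages_hv = rng.uniform(*cfg.hv_age_range, size=cfg.n_hv)
    ages_ms = np.concatenate([
        rng.normal(*cfg.subtype_age[st], size=n)
        for st, n in (("RRMS", cfg.n_rrms), ("SPMS", cfg.n_spms), ("PPMS", cfg.n_ppms))])
    ages_ms = np.clip(ages_ms, *cfg.age_clip)
    ages = np.concatenate([ages_hv, ages_ms])
    sex = (rng.random(cfg.n_hv + cfg.n_ms) < cfg.p_female).astype(int)  # 1 = female
    is_ms = np.concatenate([np.zeros(cfg.n_hv, bool), np.ones(cfg.n_ms, bool)])
    n = len(ages)

    # panel: baseline + age/sex effects + module factor + residual; baselines
    # come from the analyte seed (shared across cohorts of one study)
    aseed = cfg.seed if cfg.analyte_seed is None else cfg.analyte_seed
    arng = np.random.default_rng(np.random.SeedSequence(entropy=int(aseed),
                                                        spawn_key=(424242,)))
    baseline = cfg.baseline_mean + cfg.baseline_sd * arng.standard_normal(p)
    hv_slopes = truth_a["hv_age_slope"].to_numpy()
    ms_slopes = truth_a["ms_age_slope"].to_numpy()
    slopes = np.where(is_ms[:, None], ms_slopes[None, :], hv_slopes[None, :])
    x = baseline[None, :] + slopes * ages[:, None]
    x += sex[:, None] * truth_a["sex_effect"].to_numpy()[None, :]

    n_modules = len(cfg.module_sizes)
    factors = rng.standard_normal((n, n_modules))
    module_id = truth_a["module_id"].to_numpy()
    is_member = module_id > 0
    x[:, is_member] += cfg.module_loading * factors[:, module_id[is_member] - 1]

    resid_sd = np.where(is_member, cfg.module_resid_sd, cfg.resid_sd)
    x += resid_sd[None, :] * rng.standard_normal((n, p))

    # latent severity = weighted sum of module analyte values + noise
    w = truth_a["severity_weight"].to_numpy()
    severity = x @ w + cfg.severity_noise_sd * rng.standard_normal(n)
    severity = severity - severity.mean() + cfg.severity_mu
    sev_sd = severity.std()
    severity_z = (severity - severity.mean()) / (sev_sd if sev_sd > 0 else 1.0)

    bpfr, deficit = generate_brain_volume(ages, cfg, rng, severity_z)

    sample_ids = hv_ids + ms_ids
    panel = pd.DataFrame(x, index=pd.Index(sample_ids, name="sample_id"),
                         columns=truth_a.index)

    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": sample_ids,
        "cohort": ["HV"] * cfg.n_hv + ["MS"] * cfg.n_ms,
        "subtype": ["NA"] * cfg.n_hv + subtypes,
        "age": ages,
        "sex": np.where(sex == 1, "F", "M"),
        "visit_index": 0,
    }).set_index("sample_id", drop=False)
    meta["sex_indicator"] = sex
    meta["msdss_baseline"] = np.where(is_ms, severity, np.nan)
    meta["msdss_followup"] = np.where(
        is_ms, severity + cfg.followup_noise_sd * rng.standard_normal(n), np.nan)
    meta["bpfr"] = bpfr
    meta["progression_slope"] = np.where(
        is_ms, severity + cfg.slope_noise_sd * rng.standard_normal(n), np.nan)
    meta["armss"] = np.where(is_ms, severity + 3.0 * rng.standard_normal(n), np.nan)
    meta["edss"] = np.where(is_ms, np.clip(np.round(2 * (2 + severity_z * 1.5)) / 2, 0, 10), np.nan)

    samples = pd.DataFrame({"latent_severity": severity, "true_deficit": deficit},
                           index=panel.index)
    truth = SyntheticTruth(analytes=truth_a, samples=samples, config=cfg)
    return panel, meta, _reference_table(truth_a), truth


def generate_longitudinal_severity(cfg: SimulationConfig, n_subjects: int | None = None):
    """Repeated severity measurements with subject random intercepts.

    severity_ij = mu + b_i + e_ij with Var(b) = sigma_between_sq and
    Var(e) = sigma_within_sq; the population ICC is
    sigma_between_sq / (sigma_between_sq + sigma_within_sq).
    """
    if cfg.k_visits < 2:
        raise ValueError(f"need k >= 2 visits, got {cfg.k_visits}")
    n = cfg.n_ms if n_subjects is None else n_subjects
    rng = np.random.default_rng(cfg.seed)
    b = np.sqrt(cfg.sigma_between_sq) * rng.standard_normal(n)
    e = np.sqrt(cfg.sigma_within_sq) * rng.standard_normal((n, cfg.k_visits))
    sev = cfg.severity_mu + b[:, None] + e
    return pd.DataFrame({
        "subject_id": np.repeat([f"MS{i:03d}" for i in range(n)], cfg.k_visits),
        "visit_index": np.tile(np.arange(cfg.k_visits), n),
        "severity": sev.ravel(),
    })
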