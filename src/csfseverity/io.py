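"""Readers and writers for the tabular interchange formats.

Panel files are wide sample x analyte tables (first column ``sample_id``) in
relative fluorescence units (RFU).  All analyte values are carried internally
as natural-log RFU; ``log_input`` states whether the file is pre-logged.
Metadata and reference tables are plain TSV/CSV; the delimiter is
auto-detected between tab and comma.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, config_hash

logger = logging.getLogger("csfseverity")

__all__ = [
    "read_panel",
    "read_metadata",
    "read_reference",
    "read_inputs",
    "write_table",
    "write_results_bundle",
    "SEX_CODES",
    "COHORT_CODES",
]

#: sex indicator: M (reference level) -> 0, F -> 1
SEX_CODES = {"M": 0, "F": 1}
COHORT_CODES = ("HV", "MS")
SUBTYPE_CODES = ("RRMS", "SPMS", "PPMS")

REQUIRED_METADATA = ["sample_id", "subject_id", "cohort", "subtype",
                     "age", "sex", "visit_index"]
OPTIONAL_OUTCOMES = ["msdss_baseline", "msdss_followup", "armss", "msss", "edss",
                     "bpfr", "progression_slope", "snfl", "cnfl"]


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_panel(path: str | Path, log_input: bool = False) -> pd.DataFrame:
    """Read a wide analyte panel; returns natural-log RFU indexed by sample_id.

    Raw-RFU files must be strictly positive (the natural log is applied on
    load); duplicated sample or analyte IDs are fatal.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.columns[0] != "sample_id":
        raise ValueError(f"panel first column must be 'sample_id', got {df.columns[0]!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicated sample IDs in panel: {dup}")
    df = df.set_index("sample_id")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicated analyte IDs: {df.columns[df.columns.duplicated()].tolist()}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = df.columns[np.isnan(values).any(axis=0)].tolist()
        raise ValueError(f"missing values are not supported; offending analytes: {bad}")
    if not log_input:
        if (values <= 0).any():
            bad = df.columns[(values <= 0).any(axis=0)].tolist()
            raise ValueError(
                "raw-RFU panel contains non-positive values, cannot apply the "
                f"natural-log transform; offending analytes: {bad}")
        df = np.log(df)
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; validates codes and adds a ``sex_indicator`` column."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c in REQUIRED_METADATA if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicated sample IDs in metadata: {dup}")
    bad_sex = sorted(set(df["sex"]) - set(SEX_CODES))
    if bad_sex:
        raise ValueError(f"unknown sex codes {bad_sex}; expected {sorted(SEX_CODES)}")
    bad_cohort = sorted(set(df["cohort"]) - set(COHORT_CODES))
    if bad_cohort:
        raise ValueError(f"unknown cohort codes {bad_cohort}; expected {list(COHORT_CODES)}")
    df = df.set_index("sample_id", drop=False)
    df["sex_indicator"] = df["sex"].map(SEX_CODES).astype(int)
    return df


def read_reference(path: str | Path) -> pd.DataFrame:
    """Read the external serum reference coefficient table."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = ["analyte_id", "covariate", "coefficient", "significant"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"reference table missing columns: {missing}")
    bad = sorted(set(df["covariate"]) - {"age", "sex"})
    if bad:
        raise ValueError(f"unknown covariates in reference table: {bad}")
    df["significant"] = df["significant"].astype(bool)
    return df


def read_inputs(config: PipelineConfig):
    """Load panel, metadata and reference table; align sample order.

    Returns ``(panel, metadata, reference)`` with the panel rows reordered to
    the metadata sample order.  Sample-ID mismatches are fatal.
    """
    config.resolve_paths()
    panel = read_panel(config.panel_path, log_input=config.log_input)
    meta = read_metadata(config.metadata_path)
    reference = read_reference(config.reference_path)
    only_panel = sorted(set(panel.index) - set(meta.index))
    only_meta = sorted(set(meta.index) - set(panel.index))
    if only_panel or only_meta:
        raise ValueError(
            f"sample IDs do not match: panel-only={only_panel}, metadata-only={only_meta}")
    panel = panel.loc[meta.index]
    n_hv = int((meta["cohort"] == "HV").sum())
    logger.info("loaded %d samples x %d analytes (%d HV, %d MS)",
                panel.shape[0], panel.shape[1], n_hv, panel.shape[0] - n_hv)
    return panel, meta, reference


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def write_results_bundle(results: dict, outdir: str | Path,
                         config: PipelineConfig | None = None,
                         seed: int | None = None) -> dict:
    """Write a deterministic results bundle plus a manifest.

    ``results`` maps file stems to DataFrames (written as TSV) or plain
    dicts/lists (written as JSON).  The manifest records the emitted files,
    the configuration hash and the master seed, so two runs with identical
    inputs and seed produce byte-identical numeric tables.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    files = []
    for stem, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            name = f"{stem}.tsv"
            write_table(obj, outdir / name)
        else:
            name = f"{stem}.json"
            with open(outdir / name, "w") as fh:
                json.dump(obj, fh, indent=1, sort_keys=True, default=float)
        files.append(name)
    manifest = {
        "files": sorted(files),
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "config": asdict(config) if config is not None else None,
        "sex_reference_level": "M",
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
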