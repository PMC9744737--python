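"""Pipeline configuration and deterministic seed management.

A single master seed drives every stochastic stage.  Each stage derives its
own child seed through a fixed counter scheme (``child_seed``), so stages are
individually reproducible and independent of execution order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RFParams", "PipelineConfig", "child_seed", "config_hash", "STAGE_INDEX"]

# Fixed stage -> counter mapping.  Adding a stage appends a new index; existing
# indices never change, so seeds stay stable across versions.
STAGE_INDEX = {
    "simulate": 0,
    "adjust": 1,
    "clock": 2,
    "outcomes": 3,
    "screen": 4,
    "train": 5,
    "evaluate": 6,
    "cluster": 7,
    "split": 8,
}


def child_seed(master_seed: int, stage: str, repeat: int = 0) -> int:
    """Derive a stage-specific 31-bit seed from the master seed.

    ``repeat`` distinguishes repeated invocations of the same stage (e.g. the
    ten forests fitted at one elimination step derive their own seeds one
    level further down).
    """
    if stage not in STAGE_INDEX:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(STAGE_INDEX)}")
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(STAGE_INDEX[stage], int(repeat)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RFParams:
    """Random-forest selection/fit parameters.

    The elimination loop fits ``n_forests_per_step`` forests per step, drops
    the ``drop_fraction`` least important features (at least one) and stops at
    ``floor`` features.  ``mtry`` follows the 3*sqrt(p) rule, rounded half-up
    and clipped to [1, p].  ``min_node_size`` is the regression default of the
    ranger forest implementation.
    """

    n_forests_per_step: int = 10
    drop_fraction: float = 0.10
    floor: int = 3
    ntree_selection: int = 200
    ntree_final: int = 40_000
    min_node_size: int = 5
    oob_rule: str = "min"  # cut at the OOB-error minimum; "1se" for the 1-SE rule

    def __post_init__(self) -> None:
        if not 0 < self.drop_fraction < 1:
            raise ValueError(f"drop_fraction must be in (0,1), got {self.drop_fraction}")
        if self.floor < 1:
            raise ValueError(f"floor must be >= 1, got {self.floor}")
        if self.ntree_selection < 1 or self.ntree_final < 1:
            raise ValueError("ntree parameters must be >= 1")
        if self.n_forests_per_step < 1:
            raise ValueError("n_forests_per_step must be >= 1")
        if self.oob_rule not in ("1se", "min"):
            raise ValueError(f"oob_rule must be '1se' or 'min', got {self.oob_rule!r}")

    @staticmethod
    def mtry(p: int) -> int:
        """mtry = 3*sqrt(p), rounded half-up, clipped to [1, p]."""
        return min(p, max(1, int(3.0 * np.sqrt(p) + 0.5)))


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Thresholds are two-sided alphas; ``tier1_alpha`` applies to the
    reference-prioritized screen and ``tier2_family_alpha`` is the family-wise
    (Bonferroni) level for the remaining analytes.
    """

    panel_path: str = ""
    metadata_path: str = ""
    reference_path: str = ""
    log_input: bool = False  # True if the panel file is already natural-log RFU
    tier1_alpha: float = 0.05
    tier2_family_alpha: float = 0.05
    rf: RFParams = field(default_factory=RFParams)
    n_train: int = 129
    n_valid: int = 98
    k_modules: int = 4
    k_patients: int = 7
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        for name in ("tier1_alpha", "tier2_family_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if isinstance(self.rf, dict):
            self.rf = RFParams(**self.rf)
        if self.k_modules < 1 or self.k_patients < 1:
            raise ValueError("cluster counts must be >= 1")

    def resolve_paths(self) -> None:
        """Fail early if any configured input file is missing."""
        for name in ("panel_path", "metadata_path", "reference_path"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the full configuration (changes iff any field changes)."""
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
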