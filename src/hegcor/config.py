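"""Run configuration with the published default thresholds.

Every numeric default traces to the reference analysis protocol: the 10%
heritability floor, 5-SD outlier rule, alpha = 0.05 permutation level with
1,000 permutations, the global LOD >= 6 reporting threshold, and the
drop = 2 / peakdrop = 3 peak-calling geometry.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclasses.dataclass
class RunConfig:
    out_dir: str = "hegcor_run"
    # simulation inputs (used when no external data paths are given)
    n_individuals: int = 500
    n_markers: int = 1000
    n_causal: int = 10
    # external inputs (optional; override simulation)
    pheno_path: str | None = None
    covar_path: str | None = None
    probs_path: str | None = None
    kinship_path: str | None = None
    diet_numeric: bool = False
    # thresholds (published defaults)
    h2_min: float = 0.10          # heritability floor for high-confidence traits
    outlier_sd: float = 5.0       # outlier exclusion rule
    alpha: float = 0.05           # permutation significance level
    n_perm: int = 1000            # unrestricted permutations
    lod_global: float = 6.0       # global reporting threshold
    drop: float = 2.0             # support-interval drop
    peakdrop: float = 3.0         # peak-separation dip
    # clustering
    k_min: int = 2
    k_max: int | None = None
    # randomness: one root seed, split per stage
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("h2_min", "outlier_sd", "alpha", "lod_global", "drop", "peakdrop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pheno_path", "covar_path", "probs_path", "kinship_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} = {p} does not exist")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        h = 0
        for ch in stage:
            h = (h * 131 + ord(ch)) % (2**31 - 1)
        return (self.seed * 1_000_003 + h) % (2**31 - 1)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
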