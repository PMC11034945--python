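"""Pipeline configuration: printed constants of the analysis, serializable to YAML."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # promoter window relative to the TSS, strand-aware
    promoter_up: int = 4000
    promoter_down: int = 1000
    # motif-scan window centered on peak summits
    motif_window: int = 150
    # genome-binned clustering
    bin_size: int = 5000
    # low-count filter: drop features with < min_count reads in over
    # min_sample_frac of samples
    min_count: int = 20
    min_sample_frac: float = 0.5
    # personalized PageRank
    damping: float = 0.85
    ppr_tol: float = 1e-8
    # significance and reversal thresholds
    fdr_alpha: float = 0.05
    ppr_delta_threshold: float = 0.5
    age_r_threshold_neuron: float = 0.50
    age_r_threshold_glia: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.damping < 1:
            raise ValueError(f"damping {self.damping} not in (0, 1)")
        if self.ppr_tol <= 0:
            raise ValueError("ppr_tol must be positive")
        if not 0 < self.min_sample_frac <= 1:
            raise ValueError("min_sample_frac must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable short hash of the full configuration (for run manifests)."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
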