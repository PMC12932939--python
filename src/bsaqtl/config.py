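"""Run configuration: every stage parameter with its standard default.

Defaults follow the analysis conventions: 1-Mb windows on a 100-kb step,
SNP-index floor 0.3, depth floor 7, 1,000 permutation iterations, 95th
percentile threshold, |log2FC| > 1 with FDR < 0.05 for the DEG join, and
priority at |fold change| > 4. The config serializes verbatim into the run
manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # inputs
    vcf: str = ""
    gff3: str = ""
    cds_fasta: str = ""
    deg: str = ""
    phenotypes: str = ""
    # marker selection
    min_parent_depth: int = 7
    max_minor_fraction: float = 0.1
    track: str = "parent_b"
    # SNP-index filters
    min_index: float = 0.3
    min_depth: int = 7
    # genome scan
    window_bp: int = 1_000_000
    step_bp: int = 100_000
    min_markers: int = 3
    n_iterations: int = 1_000
    percentile: float = 95.0
    scheme: str = "genetic_null"
    # genetic_null design parameters
    bulk_size: int = 15
    cm_per_mb: float = 3.0
    error_rate: float = 0.001
    # candidate intersection
    fc_threshold: float = 1.0  # log2 scale
    fdr_threshold: float = 0.05
    min_abs_fold_change: float = 4.0
    # reproducibility
    seed: int = 1

    #: preset matching the stricter candidate-screen thresholds
    PRESETS = {"strict": {"fc_threshold": 3.0, "fdr_threshold": 0.01}}

    def validate(self) -> None:
        if self.step_bp <= 0:
            raise ValueError("step_bp must be positive")
        if self.window_bp < self.step_bp:
            raise ValueError("window_bp must be >= step_bp")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def apply_preset(self, name: str) -> "RunConfig":
        if name not in self.PRESETS:
            raise ValueError(f"unknown preset {name!r}")
        for k, v in self.PRESETS[name].items():
            setattr(self, k, v)
        return self
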