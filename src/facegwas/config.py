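"""Run configuration: QC thresholds, analysis constants, file paths."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Pipeline-wide constants.

    Defaults follow standard GWAS quality-control practice for imputed data:
    minor allele frequency > 0.01, imputation info > 0.8, SNP call rate >
    0.97, Hardy-Weinberg exact p > 1e-4; phenotype outliers beyond 3 sd are
    masked; four genotype principal components are used as ancestry
    covariates; 5e-8 is the per-phenotype genome-wide significance level.
    """

    seed: int = 0
    maf_min: float = 0.01
    call_rate_min: float = 0.97
    hwe_p_min: float = 1e-4
    info_min: float = 0.8
    outlier_sd: float = 3.0
    n_pcs: int = 4
    alpha_gw: float = 5e-8
    replication_snp_count: int = 0
    clump_window_bp: int = 1_000_000
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min", "info_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        if not (0.0 < self.alpha_gw < 1.0):
            raise ValueError("alpha_gw must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a plain-text ``key: value`` configuration file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def echo(self) -> str:
        """One-line summary used in report headers."""
        d = dataclasses.asdict(self)
        d.pop("paths")
        return " ".join(f"{k}={v}" for k, v in d.items())
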