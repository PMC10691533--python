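"""Pipeline configuration.

All stage thresholds live here with their standard defaults: permutation-FDR
alpha 0.05 for the correlation cutoff, module sizes 10-500 for enrichment
eligibility, Fisher-test significance at overlap > 3 and adjusted P < 0.05,
fold change > 2 for differential expression, delta-beta > 0.2 for differential
methylation, SNP minor-allele-frequency mask at 0.05, promoter windows of
2 kb upstream / 200 bp downstream of the TSS, module conservation at Jaccard
> 0.4 with adjusted P < 0.05 (specific below 0.05 / above 0.05), aggregated
network node weight >= 4, and Cox significance at P < 0.05.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # preprocess
    max_bad_fraction: float = 0.75
    log2_offset: float = 1.0
    apply_log2: bool = True
    covariates: tuple[str, ...] = ("age", "sex", "race")

    # network
    corr_fdr_alpha: float = 0.05
    n_corr_permutations: int = 10
    corr_grid_step: float = 0.01
    min_module_size: int = 10
    max_module_size: int = 500
    hub_permutations: int = 100
    hub_alpha: float = 0.05

    # enrichment
    min_overlap: int = 4  # "overlap greater than three"
    enrichment_alpha: float = 0.05

    # prognosis
    cox_alpha: float = 0.05
    cox_mode: str = "median-split"  # or "continuous"
    endpoint_per_cohort: dict[str, str] = field(default_factory=dict)

    # epigenomics
    fc_threshold: float = 2.0
    deg_alpha: float = 0.05
    delta_beta_threshold: float = 0.2
    dmc_alpha: float = 0.05
    maf_cutoff: float = 0.05
    promoter_upstream: int = 2000
    promoter_downstream: int = 200

    # preservation
    jaccard_conserved: float = 0.4
    jaccard_specific: float = 0.05
    preservation_alpha: float = 0.05
    min_aggregation_weight: int = 4
    cohort_cluster_cut: float = 0.7

    # run
    seed: int = 0
    input_dir: str = "."
    output_dir: str = "results"

    def validate(self) -> None:
        if not 0 < self.max_bad_fraction <= 1:
            raise ValueError("max_bad_fraction must be in (0, 1]")
        for name in ("corr_fdr_alpha", "enrichment_alpha", "cox_alpha",
                     "deg_alpha", "dmc_alpha", "preservation_alpha", "hub_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_module_size < 2 or self.max_module_size < self.min_module_size:
            raise ValueError("invalid module size bounds")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.delta_beta_threshold < 1:
            raise ValueError("delta_beta_threshold must be in (0, 1)")
        if self.cox_mode not in ("median-split", "continuous"):
            raise ValueError("cox_mode must be 'median-split' or 'continuous'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["covariates"] = list(d["covariates"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
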