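"""Run configuration: every numeric threshold of the framework, named once.

Stage code takes its constants from here (or from the dataclasses that this
module assembles), never as inline literals, so a run is fully described by
one YAML document.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .nominate import NominationConfig
from .variants import FilterThresholds

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults are the framework's stated operating values."""

    seed: int = 0
    # hard filters
    af_monoallelic: float = 1e-3
    af_biallelic: float = 1e-2
    gerp_min: float = 2.0
    gq_min: float = 20.0
    ab_min: float = 0.15
    # SV / TE gates
    sv_cohort_af_max: float = 5e-3
    te_af_dominant_max: float = 1e-2
    te_af_de_novo_max: float = 0.0
    te_padding: int = 15
    sv_multihit_max_span: int = 100_000
    # peak-to-gene linking
    link_window: int = 500_000
    gene_rank_window: int = 50_000
    link_r_min: float = 0.1
    link_fdr_max: float = 1e-4
    # permutation enrichment
    permutation_iterations: int = 5000
    de_novo_outlier_threshold: int = 75
    # effect scores
    sad_z_threshold: float = 2.0
    # promoter definition for context labels
    promoter_upstream: int = 2000
    promoter_downstream: int = 200
    # cohort curation
    family_blocklist: list[str] = field(default_factory=list)
    known_genes: list[str] = field(default_factory=list)

    def filter_thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            af_monoallelic=self.af_monoallelic,
            af_biallelic=self.af_biallelic,
            gerp_min=self.gerp_min, gq_min=self.gq_min, ab_min=self.ab_min,
        )

    def nomination_config(self) -> NominationConfig:
        return NominationConfig(
            thresholds=self.filter_thresholds(),
            sv_cohort_af_max=self.sv_cohort_af_max,
            te_af_dominant_max=self.te_af_dominant_max,
            te_af_de_novo_max=self.te_af_de_novo_max,
            te_padding=self.te_padding,
            sv_multihit_max_span=self.sv_multihit_max_span,
            family_blocklist=frozenset(self.family_blocklist),
            known_genes=tuple(self.known_genes),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
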