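"""Pipeline configuration.

Defaults follow the study design: 1,000 bootstrap replicates, recombination
significance at p <= 0.03, per-site selection significance at p <= 0.1,
complete deletion of gapped/ambiguous columns, and a locus-calling distance
threshold of 0.02 substitutions/site sitting between the observed intra-locus
polymorphism ceiling (~0.008) and the inter-locus divergence floor (~0.04).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    locus_distance_threshold: float = 0.02
    support_threshold: float = 70.0
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    window_codons: int = 20
    step_codons: int = 5
    recombination_p_max: float = 0.03
    recombination_permutations: int = 1000
    recombination_correction: str = "bonferroni"  # or "none"
    site_test_p_max: float = 0.1
    gap_policy: str = "complete_deletion"  # or "pairwise_deletion"
    min_evidence_count: int = 2
    min_orf_aa: int = 80
    dnds_bootstrap_reps: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.locus_distance_threshold < 1:
            raise ValueError("locus_distance_threshold must be in (0,1)")
        if not 0 < self.recombination_p_max <= 1:
            raise ValueError("recombination_p_max must be in (0,1]")
        if not 0 < self.site_test_p_max <= 1:
            raise ValueError("site_test_p_max must be in (0,1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.gap_policy not in ("complete_deletion", "pairwise_deletion"):
            raise ValueError(f"unknown gap_policy {self.gap_policy!r}")
        if self.recombination_correction not in ("bonferroni", "none"):
            raise ValueError("recombination_correction: bonferroni or none")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
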