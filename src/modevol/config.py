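"""Pipeline configuration.

Thresholds follow the comparative wood-decay study design: FDR 0.05 with
|log2FC| > 1 for differential expression, MCL inflation 3 and BLAST-style
similarity cutoffs (e-value 1e-5, percent match 25) for orthogroup
construction, and Fisher/BH at alpha 0.05 for enrichment.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml


@dataclasses.dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with study defaults.

    Attributes
    ----------
    fdr_alpha : float
        BH-adjusted p-value cutoff for calling a gene significantly induced.
    lfc_min : float
        Minimum absolute log2 fold change for induction calls.
    mcl_inflation : float
        Inflation exponent of the Markov clustering step.
    similarity_evalue_max : float
        Maximum e-value for a similarity hit to enter the graph.
    percent_match_min : float
        Minimum percent identity/match for a similarity hit.
    enrichment_alpha : float
        BH cutoff for flagging enriched terms.
    cpm_filter_min, cpm_filter_min_samples :
        A gene is tested only if CPM >= cpm_filter_min in at least
        cpm_filter_min_samples samples.
    prior_count : float
        Prior count for regularized log2-CPM.
    rng_seed : int
        Seed for any stochastic step (only the simulator uses randomness).
    """

    fdr_alpha: float = 0.05
    lfc_min: float = 1.0
    mcl_inflation: float = 3.0
    similarity_evalue_max: float = 1e-5
    percent_match_min: float = 25.0
    enrichment_alpha: float = 0.05
    cpm_filter_min: float = 1.0
    cpm_filter_min_samples: int = 2
    prior_count: float = 0.5
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError(f"fdr_alpha must be in (0, 1), got {self.fdr_alpha}")
        if self.lfc_min < 0:
            raise ValueError(f"lfc_min must be >= 0, got {self.lfc_min}")
        if self.mcl_inflation <= 1:
            raise ValueError(f"mcl_inflation must be > 1, got {self.mcl_inflation}")
        if not 0.0 < self.enrichment_alpha < 1.0:
            raise ValueError("enrichment_alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML (or JSON) mapping; unknown keys rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
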