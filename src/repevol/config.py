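"""Pipeline configuration: species/branch labels, thresholds, model options.

Round-trips losslessly through YAML. All downstream randomness (bootstrap,
contrast Monte Carlo) derives deterministically from the single top-level
seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .tree import DEFAULT_TAXA, LabeledTree


@dataclass
class PipelineConfig:
    taxa: tuple[str, ...] = DEFAULT_TAXA          # (SC, SC, SI, SI) order
    voting_species: tuple[str, ...] = ("lycopersicum", "pennellii", "habrochaites")
    expressed_tpm: float = 2.0
    trace_tpm: float = 0.5
    min_codons: int = 67                           # > 200 bp after cleaning
    omega_ceiling: float = 10.0
    freq_scheme: str = "F3x4"
    branch_scheme: str = "THREE_RATIO"
    bootstrap_reps: int = 1000
    bootstrap_sample_size: int = 500
    bootstrap_replace: bool = True
    seed: int = 0
    taxon_aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        self.voting_species = tuple(self.voting_species)
        if self.expressed_tpm <= 0 or self.trace_tpm <= 0 or self.min_codons <= 0:
            raise ValueError("thresholds must be positive")
        if len(self.taxa) != 4:
            raise ValueError("exactly four taxa required")

    def tree(self) -> LabeledTree:
        return LabeledTree(taxa=self.taxa)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fanned out from the top-level seed."""
        h = int(self.seed) & 0xFFFFFFFF
        for ch in stage:
            h = (h * 31 + ord(ch)) & 0xFFFFFFFF
        return h % (2**31 - 1)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["taxa"] = list(self.taxa)
        data["voting_species"] = list(self.voting_species)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("taxa", "voting_species"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
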