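"""Run configuration: one place where every analysis default lives.

Defaults encode the documented pipeline constants — q-value input filter
0.01, Welch alpha 0.05 (no correction; the all-replicates filter is the
de-facto error control), trace fraction 0.02 (= 50-fold, boundary
inclusive), evidence experimental-channel threshold 700, fragment match
tolerance 0.05 Da, localization confidence bands 15-19 and >19, peptide
lengths 6-40 and the +79.9663 Da phospho delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from apmsflow.errors import ConfigError
from apmsflow.phospho import DEPTH_WEIGHTS


@dataclass
class RunConfig:
    # paths
    psm_dir: str = ""
    fasta: str = ""
    evidence: str = ""
    annotations: str = ""
    spectra_mgf: str = ""
    spectra_assignments: str = ""
    output_dir: str = "out"
    # identity
    bait_accession: str = ""
    # parameters
    q_value_max: float = 0.01
    alpha: float = 0.05
    bh_correct: bool = False
    min_peptides: int = 2
    min_peptides_granularity: str = "band"
    trace_fraction: float = 0.02
    trace_inclusive: bool = True
    evidence_min_score: int = 700
    tolerance_da: float = 0.05
    depth_weights: tuple[float, ...] = DEPTH_WEIGHTS
    n_phospho: int = 1
    mature_offset: int = 0
    ambiguity_threshold: float = 15.0
    ascore_mid_band: tuple[float, float] = (15.0, 19.0)
    node_size_range: tuple[float, float] = (10.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.depth_weights = tuple(self.depth_weights)
        self.ascore_mid_band = tuple(self.ascore_mid_band)
        self.node_size_range = tuple(self.node_size_range)
        if not 0 < self.trace_fraction < 1:
            raise ConfigError(f"trace_fraction must be in (0, 1), got {self.trace_fraction}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_peptides_granularity not in ("band", "sample"):
            raise ConfigError("min_peptides_granularity must be 'band' or 'sample'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = {}
        for f in fields(self):
            value = getattr(self, f.name)
            payload[f.name] = list(value) if isinstance(value, tuple) else value
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
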