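"""Pipeline configuration.

One dataclass holds every tunable of the pipeline, with defaults equal
to the module-level defaults (significance threshold 2.5, ratio_min 2,
peptide_min 2, pseudocount 1, top-2 hit reporting). The config
round-trips through YAML so a manifest can echo it verbatim.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .enrichment import (
    DEFAULT_PEPTIDE_MIN,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_RATIO_MIN,
)
from .scanner import DEFAULT_THRESHOLD

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds of one pipeline run."""

    # inputs
    fasta: str | None = None
    psm_table: str | None = None
    ortholog_map: str | None = None
    screen_table: str | None = None
    conventional_matrix: str | None = None  # None -> bundled default
    phospho_matrix: str | None = None
    # outputs
    out_dir: str = "triage_out"
    # thresholds
    significance_threshold: float = DEFAULT_THRESHOLD
    ratio_min: float = DEFAULT_RATIO_MIN
    peptide_min: int = DEFAULT_PEPTIDE_MIN
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    top_k: int = 2
    # windows overhanging a terminus are never scored; kept explicit so
    # the manifest records the behaviour
    terminal_mode: str = "contained"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
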