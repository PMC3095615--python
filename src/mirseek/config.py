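"""Pipeline configuration: every stage threshold in one round-trippable object."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds of the discovery pipeline.

    Defaults are the analysis' canonical settings: the 18-30 nt read window,
    the +/- 2 nt end-shift rule for known-miRNA and star matching, exclusion
    of tags with more than 50 genomic loci as repeat-associated siRNAs,
    duplexes with at least 16 matched pairs and mature/star size difference
    at most 4 nt, the 5-read Class B abundance floor, and the 4.0 target
    score cutoff.
    """

    min_len: int = 18
    max_len: int = 30
    adapter_3p: str | None = None
    adapter_min_overlap: int = 6
    end_shift: int = 2
    max_mismatch: int = 0
    max_loci: int = 50
    flank_lengths: tuple[int, ...] = (100, 170, 250)
    near_flank: int = 60
    min_matched_pairs: int = 16
    max_size_diff: int = 4
    overhang: int = 2
    class_b_min_reads: int = 5
    target_max_score: float = 4.0
    seed: int = 0

    def __post_init__(self):
        self.flank_lengths = tuple(self.flank_lengths)
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")
        if self.end_shift < 0 or self.end_shift > 5:
            raise ValueError("end_shift outside [0, 5]")
        if self.max_mismatch < 0 or self.max_mismatch > 2:
            raise ValueError("max_mismatch outside [0, 2]")
        if self.max_loci < 1:
            raise ValueError("max_loci must be >= 1")
        if any(f <= 0 for f in self.flank_lengths) or self.near_flank <= 0:
            raise ValueError("flank lengths must be positive")
        if self.min_matched_pairs < 1 or self.max_size_diff < 0:
            raise ValueError("invalid duplex thresholds")
        if self.class_b_min_reads < 1 or self.target_max_score < 0:
            raise ValueError("invalid class/target thresholds")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flank_lengths"] = list(self.flank_lengths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
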