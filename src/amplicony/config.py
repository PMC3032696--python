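"""Run configuration.

All fixed analysis parameters live here with their working defaults:
2 x 36 bp reads, <=2 mismatches per mate, 200-300 bp inserts, word size
10 for dot-plots, the two BAC-overlap assembly tiers (>=99.99% identity
over >=30 kb, relaxed >=99.85% over >=20 kb), the active-ORF thresholds,
1000 bootstrap replicates, and the 19.6 Mya cattle/sheep split used to
calibrate duplication ages.  Every value can be overridden from a YAML
file; each run directory receives a snapshot for reproducibility.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    read_length: int = 36
    max_mismatches: int = 2
    insert_min: int = 200
    insert_max: int = 300
    dotplot_word: int = 10
    assembly_min_identity: float = 0.9999
    assembly_min_overlap: int = 30000
    relaxed_min_identity: float = 0.9985
    relaxed_min_overlap: int = 20000
    active_min_aa: int = 200
    active_min_fraction: float = 0.40
    bootstrap_reps: int = 1000
    calibration_time: float = 19.6

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "read_length": self.read_length,
            "max_mismatches": self.max_mismatches + 1,  # 0 mismatches allowed
            "insert_min": self.insert_min,
            "insert_max": self.insert_max,
            "dotplot_word": self.dotplot_word,
            "assembly_min_overlap": self.assembly_min_overlap,
            "relaxed_min_overlap": self.relaxed_min_overlap,
            "active_min_aa": self.active_min_aa,
            "bootstrap_reps": self.bootstrap_reps,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in ("assembly_min_identity", "relaxed_min_identity",
                     "active_min_fraction"):
            value = getattr(self, name)
            if not (0 < value <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min must be <= insert_max")
        if self.read_length > self.insert_min:
            raise ValueError("read_length must be <= insert_min")
        if self.calibration_time <= 0:
            raise ValueError("calibration_time must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
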