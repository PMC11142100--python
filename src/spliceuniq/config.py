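"""Analysis thresholds, loadable from a flat YAML file.

Defaults mirror the conservative filtering used throughout the analysis:
a junction-read floor of 5, effect-size gate |ΔPSI| > 0.10, p < 0.05 and
BH q < 0.05 for splicing; p < 0.01 and |log2FC| > 2 for expression; and a
minimum of 5 pairwise calls for an event to enter global totals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .types import SpliceUniqError


@dataclass(frozen=True)
class Thresholds:
    junction_min_reads: int = 5
    delta_psi_min: float = 0.10
    p_max: float = 0.05
    q_max: float = 0.05
    expr_p_max: float = 0.01
    expr_lfc_min: float = 2.0
    global_min_comparisons: int = 5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise SpliceUniqError(f"threshold {f.name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SpliceUniqError(f"unknown threshold keys in {path}: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_THRESHOLDS = Thresholds()
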