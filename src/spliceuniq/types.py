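"""Core domain containers shared across the pipeline.

Coordinates are 1-based inclusive genomic positions throughout the in-memory
model; BED-like on-disk exports convert to 0-based half-open (and say so in
their header).  PSI is stored as a fraction in [0, 1]; missing (undetected)
is ``NaN`` and is distinct from a PSI of 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

#: The six splicing-event classes emitted by junction-based event callers:
#: cassette exons, mutually exclusive exons, alternative 5'/3' splice sites,
#: intron retention, and composite (intertwined) arrangements.
AS_TYPES: tuple[str, ...] = ("CASSETTE", "MXE", "A5S", "A3S", "IR", "COMPOSITE")

STRANDS = ("+", "-")


class SpliceUniqError(ValueError):
    """Raised on malformed inputs or contract violations."""


@dataclass(frozen=True)
class EventAnnotation:
    """One annotated splicing event: type, strand and its ordered sub-junctions.

    ``starts``/``ends`` are parallel tuples of 1-based inclusive genomic
    coordinates, one entry per sub-junction.  ``inclusion_index`` flags the
    sub-junction whose usage is the inclusion (cassette) or retention (IR)
    signal; it is required for CASSETTE and IR events.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    as_type: str
    starts: tuple[int, ...]
    ends: tuple[int, ...]
    inclusion_index: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise SpliceUniqError(f"{self.event_id}: strand must be + or -, got {self.strand!r}")
        if self.as_type not in AS_TYPES:
            raise SpliceUniqError(f"{self.event_id}: unknown AS type {self.as_type!r}")
        if len(self.starts) != len(self.ends):
            raise SpliceUniqError(f"{self.event_id}: starts/ends length mismatch")
        if len(self.starts) < 2:
            raise SpliceUniqError(f"{self.event_id}: an event needs >=2 sub-junctions")
        for s, e in zip(self.starts, self.ends):
            if s > e:
                raise SpliceUniqError(f"{self.event_id}: sub-junction start {s} > end {e}")
        if self.inclusion_index is not None and not (0 <= self.inclusion_index < len(self.starts)):
            raise SpliceUniqError(f"{self.event_id}: inclusion_index out of range")

    @property
    def n_subjunctions(self) -> int:
        return len(self.starts)

    def subjunction_order(self) -> list[int]:
        """Sub-junction indices sorted genomically by (start, end)."""
        return sorted(range(len(self.starts)), key=lambda i: (self.starts[i], self.ends[i]))

    def first_junction(self) -> int:
        """Index of the most upstream-by-coordinate sub-junction (smallest
        genomic start, ties broken by smaller end)."""
        return self.subjunction_order()[0]


#: Event annotations keyed by event_id (insertion-ordered).
Annotations = dict[str, EventAnnotation]


@dataclass
class SampleMap:
    """Sample → (cell type, replicate) assignment.

    Wraps a DataFrame with columns ``sample_id``, ``cell_type``,
    ``replicate_index`` (1-based).  Cell-type order is order of first
    appearance, which keeps all downstream outputs deterministic.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "cell_type", "replicate_index"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise SpliceUniqError(f"sample map missing columns: {missing}")
        self.frame = self.frame[required].reset_index(drop=True)
        if self.frame["sample_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise SpliceUniqError(f"duplicate sample ids: {dupes}")
        if (self.frame["replicate_index"] < 1).any():
            raise SpliceUniqError("replicate_index must be a positive integer")
        counts = self.frame["cell_type"].value_counts()
        singletons = counts[counts < 2].index.tolist()
        if singletons:
            warnings.warn(
                f"cell types with a single replicate: {sorted(singletons)}; "
                "differential tests need >=2",
                stacklevel=2,
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for ct in self.frame["cell_type"]:
            seen.setdefault(ct, None)
        return list(seen)

    def samples_for(self, cell_type: str) -> list[str]:
        sub = self.frame[self.frame["cell_type"] == cell_type]
        if sub.empty:
            raise SpliceUniqError(f"unknown cell type: {cell_type!r}")
        return sub.sort_values("replicate_index")["sample_id"].tolist()

    def n_replicates(self, cell_type: str) -> int:
        return len(self.samples_for(cell_type))


@dataclass
class PsiTable:
    """Per-sample junction usage.

    ``psi``: events × samples DataFrame of representative-junction usage
    (fraction; NaN = undetected).  ``subusage``: (event_id, subjunction_index)
    MultiIndex × samples DataFrame of per-sub-junction usage fractions, which
    sum to 1 per detected (event, sample).
    """

    psi: pd.DataFrame
    sample_map: SampleMap
    subusage: pd.DataFrame | None = None

    @property
    def event_ids(self) -> list[str]:
        return self.psi.index.tolist()


@dataclass(frozen=True)
class ComparisonResult:
    """One event in one ordered cell-pair comparison.

    ``delta_psi`` is mean PSI (representative junction) in ``cell_a`` minus
    ``cell_b``; ``delta_psi_first`` is the same difference for the event's
    most-upstream-by-coordinate sub-junction (the "first" junction), raw,
    i.e. before the A3S/A5S strand orientation correction.
    """

    event_id: str
    as_type: str
    cell_a: str
    cell_b: str
    delta_psi: float
    delta_psi_first: float
    p_value: float
    q_value: float
    significant: bool
    n_a: int
    n_b: int


_COMPARISON_COLUMNS = [
    "as_type", "event_id", "cell_a", "cell_b",
    "delta_psi", "delta_psi_first", "p_value", "q_value",
    "significant", "n_a", "n_b",
]


@dataclass
class ComparisonSet:
    """All ordered cell-pair comparison results, as a flat DataFrame."""

    frame: pd.DataFrame
    cell_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.empty:
            self.frame = pd.DataFrame(columns=_COMPARISON_COLUMNS)
        self.frame = self.frame[_COMPARISON_COLUMNS].reset_index(drop=True)
        if not self.cell_types:
            seen: dict[str, None] = {}
            for ct in pd.concat([self.frame["cell_a"], self.frame["cell_b"]]):
                seen.setdefault(ct, None)
            self.cell_types = list(seen)

    @property
    def n_ordered_pairs(self) -> int:
        n = len(self.cell_types)
        return n * (n - 1)

    def results(self) -> Iterator[ComparisonResult]:
        for row in self.frame.itertuples(index=False):
            yield ComparisonResult(
                event_id=row.event_id, as_type=row.as_type,
                cell_a=row.cell_a, cell_b=row.cell_b,
                delta_psi=float(row.delta_psi),
                delta_psi_first=float(row.delta_psi_first),
                p_value=float(row.p_value), q_value=float(row.q_value),
                significant=bool(row.significant),
                n_a=int(row.n_a), n_b=int(row.n_b),
            )


@dataclass(frozen=True)
class UniquenessRecord:
    """Signed uniqueness index of one feature in one focal cell type.

    ``index`` is the sum of significant, orientation-corrected first ΔPSIs
    (splicing) or significant log2 fold changes (expression) of the focal
    cell against every other cell type; bounded by ±(N−1) in fractional PSI
    units for splicing.
    """

    feature_id: str
    focal_cell: str
    index: float
    n_significant: int
    n_compared: int
    feature_type: str = "splicing"

    def __post_init__(self) -> None:
        if self.n_significant == 0 and self.index != 0.0:
            raise SpliceUniqError(
                f"{self.feature_id}/{self.focal_cell}: nonzero index with no significant comparisons"
            )


@dataclass(frozen=True)
class ExpressionResult:
    """One gene in one ordered cell-pair differential-expression test."""

    gene_id: str
    cell_a: str
    cell_b: str
    log2_fold_change: float
    p_value: float
    significant: bool


def check_counts_frame(frame: pd.DataFrame, context: str = "counts") -> None:
    """Validate a numeric table of non-negative integer read counts."""
    values = frame.to_numpy()
    if np.isnan(values.astype(float)).any():
        raise SpliceUniqError(f"{context}: NaN entries are not allowed")
    if (values < 0).any():
        raise SpliceUniqError(f"{context}: negative counts")
    if not np.allclose(values, np.round(values.astype(float))):
        raise SpliceUniqError(f"{context}: non-integer counts")
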