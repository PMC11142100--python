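"""Synthetic junction-count and expression datasets with known ground truth.

The generator emulates the shape of deep sorted-cell-type RNA-seq resources
(CeNGEN-style): 46 cell types with a few replicates each, six splicing-event
classes, hundreds of junction-spanning reads per event, and a small fraction
of planted cell-unique events.  Replicate-level PSI noise follows a
beta-binomial hierarchy — replicate PSI ~ Beta(μκ, (1−μ)κ) around the
cell-type mean μ, total reads ~ Poisson(depth), inclusion reads ~
Binomial(total, PSI) — the minimal model reproducing the replicate
overdispersion seen in such data.  Everything is reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    AS_TYPES,
    Annotations,
    EventAnnotation,
    SampleMap,
    SpliceUniqError,
    UniquenessRecord,
)
from .uniqueness import orientation_sign

_CHROMS = ("chrI", "chrII", "chrIII", "chrIV", "chrV", "chrX")
_DEFAULT_EVENTS_PER_TYPE = 40


@dataclass
class SimConfig:
    """Simulation parameters; defaults mirror the emulated study design."""

    n_cell_types: int = 46
    n_replicates: int | Sequence[int] = 4
    events_per_type: Mapping[str, int] | None = None  # default: 40 per class
    depth: float = 200.0           # mean total junction reads per event-sample
    concentration: float = 100.0   # beta concentration κ of replicate PSI noise
    planted_fraction: float = 0.05
    effect_size: float = 0.6       # planted PSI shift Δ (fraction)
    clip_low: float = 0.02
    clip_high: float = 0.98
    n_genes: int = 300
    expr_mean: float = 100.0       # median NB mean (lognormal across genes)
    expr_sigma_log: float = 1.0
    expr_dispersion: float = 0.1
    expr_fold_change: float = 16.0
    expr_planted_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            self.n_cell_types, self.depth, self.concentration,
            self.n_genes, self.expr_mean, self.expr_dispersion,
            self.expr_fold_change,
        ]
        if any(v <= 0 for v in positive):
            raise SpliceUniqError("SimConfig: all size/rate parameters must be positive")
        if not (0 <= self.planted_fraction <= 1) or not (0 <= self.expr_planted_fraction <= 1):
            raise SpliceUniqError("SimConfig: planted fractions must be in [0, 1]")
        if self.effect_size < 0:
            raise SpliceUniqError("SimConfig: effect size must be non-negative")

    def replicates_for(self, cell_index: int) -> int:
        if isinstance(self.n_replicates, int):
            return self.n_replicates
        return int(self.n_replicates[cell_index])

    @property
    def cell_types(self) -> list[str]:
        width = len(str(self.n_cell_types))
        return [f"CT{i + 1:0{width}d}" for i in range(self.n_cell_types)]


def _make_sample_map(config: SimConfig) -> SampleMap:
    rows = []
    for ci, cell in enumerate(config.cell_types):
        for r in range(config.replicates_for(ci)):
            rows.append({
                "sample_id": f"{cell}_r{r + 1}",
                "cell_type": cell,
                "replicate_index": r + 1,
            })
    return SampleMap(pd.DataFrame(rows))


def _event_annotation(as_type: str, index: int, chrom: str, strand: str, pos: int) -> EventAnnotation:
    """Synthetic coordinates laid out so sub-junction 0 is always the
    genomically-first one, and A3S/A5S geometry matches the class (shared
    donor / shared acceptor)."""
    eid = f"{as_type}_{index:04d}"
    gene = f"gene_{as_type}_{index:04d}"
    if as_type == "CASSETTE":
        starts, ends, incl = (pos, pos), (pos + 100, pos + 300), 0
    elif as_type == "IR":
        starts, ends, incl = (pos, pos), (pos + 50, pos + 250), 0
    elif as_type == "A3S":
        starts, ends, incl = (pos, pos), (pos + 200, pos + 400), None
    elif as_type == "A5S":
        starts, ends, incl = (pos, pos + 150), (pos + 400, pos + 400), None
    elif as_type == "MXE":
        starts, ends, incl = (pos, pos + 200), (pos + 100, pos + 300), None
    else:  # COMPOSITE
        starts, ends, incl = (pos, pos + 150, pos + 300), (pos + 100, pos + 250, pos + 400), None
    return EventAnnotation(
        event_id=eid, gene_id=gene, chrom=chrom, strand=strand,
        as_type=as_type, starts=starts, ends=ends, inclusion_index=incl,
    )


def _representative_is_first(ev: EventAnnotation) -> bool:
    # construction places the genomically-first sub-junction at index 0
    if ev.as_type in ("A5S", "A3S", "MXE"):
        return ev.strand == "+"
    return True


def simulate_splicing(
    config: SimConfig,
) -> tuple[pd.DataFrame, Annotations, SampleMap, pd.DataFrame]:
    """Simulate junction counts with planted cell-unique events.

    Returns (counts, annotations, sample_map, truth).  ``truth`` has one row
    per planted event: feature_id, focal_cell, baseline and shifted PSI, the
    representative-junction effect, and the expected sign of the oriented
    uniqueness index.  Raises when the requested effect size forces clipping
    of more than half the planted events.
    """
    rng = np.random.default_rng(config.seed)
    sample_map = _make_sample_map(config)
    cells = config.cell_types
    per_type = dict(config.events_per_type or {})

    annotations: Annotations = {}
    pos = 10_000
    for t_index, as_type in enumerate(AS_TYPES):
        n_events = int(per_type.get(as_type, _DEFAULT_EVENTS_PER_TYPE))
        for i in range(n_events):
            chrom = _CHROMS[(t_index + i) % len(_CHROMS)]
            strand = "+" if i % 2 == 0 else "-"
            annotations[f"{as_type}_{i:04d}"] = _event_annotation(
                as_type, i, chrom, strand, pos
            )
            pos += 1_000

    event_ids = list(annotations)
    n_events = len(event_ids)
    baseline = rng.uniform(0.10, 0.90, size=n_events)

    n_planted = int(round(config.planted_fraction * n_events))
    planted_idx = rng.choice(n_events, size=n_planted, replace=False) if n_planted else np.array([], dtype=int)
    focal_cells = rng.choice(len(cells), size=n_planted)
    truth_rows = []
    cell_means = np.tile(baseline[:, None], (1, len(cells)))
    n_clipped = 0
    for k, ei in enumerate(planted_idx):
        mu = baseline[ei]
        delta = config.effect_size
        if mu + delta <= config.clip_high:
            shifted = mu + delta
        elif mu - delta >= config.clip_low:
            shifted = mu - delta
        else:  # both directions clip; shift up and clip
            shifted = min(mu + delta, config.clip_high)
            n_clipped += 1
        ev = annotations[event_ids[ei]]
        cell_means[ei, focal_cells[k]] = shifted
        rep_effect = shifted - mu
        first_effect = rep_effect if _representative_is_first(ev) else -rep_effect
        oriented = orientation_sign(ev.as_type, ev.strand) * first_effect
        truth_rows.append({
            "feature_id": ev.event_id,
            "focal_cell": cells[focal_cells[k]],
            "baseline_psi": mu,
            "planted_psi": shifted,
            "effect": rep_effect,
            "direction": int(np.sign(oriented)),
        })
    if n_planted and n_clipped > 0.5 * n_planted:
        raise SpliceUniqError(
            f"effect size {config.effect_size} forces clipping of "
            f"{n_clipped}/{n_planted} planted events"
        )

    # replicate draws: beta-binomial junction counts per (event, sample)
    sample_cell_index = np.array([
        cells.index(ct) for ct in sample_map.frame["cell_type"]
    ])
    n_samples = len(sample_cell_index)
    mu_matrix = cell_means[:, sample_cell_index]               # events × samples
    kappa = config.concentration
    rep_psi = rng.beta(mu_matrix * kappa, (1.0 - mu_matrix) * kappa)
    totals = rng.poisson(config.depth, size=(n_events, n_samples))
    incl = rng.binomial(totals, rep_psi)

    max_sub = max(ev.n_subjunctions for ev in annotations.values())
    rows: dict[tuple[str, int], np.ndarray] = {}
    for ei, eid in enumerate(event_ids):
        ev = annotations[eid]
        rep = 0 if _representative_is_first(ev) else ev.n_subjunctions - 1
        remainder = totals[ei] - incl[ei]
        counts_by_sub = [None] * ev.n_subjunctions
        counts_by_sub[rep] = incl[ei]
        others = [j for j in range(ev.n_subjunctions) if j != rep]
        if len(others) == 1:
            counts_by_sub[others[0]] = remainder
        else:
            split = rng.binomial(remainder, 0.5)
            counts_by_sub[others[0]] = split
            counts_by_sub[others[1]] = remainder - split
        for j in range(ev.n_subjunctions):
            rows[(eid, j)] = counts_by_sub[j]

    counts = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    counts.index = pd.MultiIndex.from_tuples(rows, names=["event_id", "subjunction_index"])
    counts.columns = pd.Index(sample_map.sample_ids)

    truth = pd.DataFrame(
        truth_rows,
        columns=["feature_id", "focal_cell", "baseline_psi", "planted_psi", "effect", "direction"],
    )
    return counts, annotations, sample_map, truth


def simulate_expression(
    config: SimConfig,
    sample_map: SampleMap | None = None,
) -> tuple[pd.DataFrame, SampleMap, pd.DataFrame]:
    """Simulate a genes × samples negative-binomial count table with planted
    cell-unique genes (up ``expr_fold_change``-fold in one cell type)."""
    rng = np.random.default_rng(config.seed + 1)
    if sample_map is None:
        sample_map = _make_sample_map(config)
    cells = sample_map.cell_types
    genes = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    base_mean = rng.lognormal(math.log(config.expr_mean), config.expr_sigma_log, config.n_genes)

    n_planted = int(round(config.expr_planted_fraction * config.n_genes))
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False) if n_planted else np.array([], dtype=int)
    focal_cells = rng.choice(len(cells), size=n_planted)
    mean_matrix = np.tile(base_mean[:, None], (1, len(cells)))
    truth_rows = []
    for k, gi in enumerate(planted_idx):
        mean_matrix[gi, focal_cells[k]] *= config.expr_fold_change
        truth_rows.append({
            "feature_id": genes[gi],
            "focal_cell": cells[focal_cells[k]],
            "fold_change": config.expr_fold_change,
            "direction": 1,
        })

    sample_cell_index = np.array([cells.index(ct) for ct in sample_map.frame["cell_type"]])
    mu = mean_matrix[:, sample_cell_index]
    r = 1.0 / config.expr_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                         columns=sample_map.sample_ids)
    truth = pd.DataFrame(truth_rows, columns=["feature_id", "focal_cell", "fold_change", "direction"])
    return frame, sample_map, truth


def constant_psi_dataset(
    n_cell_types: int,
    n_replicates: int,
    focal_psi: float,
    other_psi: float,
    focal_index: int = 0,
    depth: int = 100,
    as_type: str = "CASSETTE",
    strand: str = "+",
    psi_by_cell: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, Annotations, SampleMap]:
    """Deterministic one-event dataset with exact replicate PSI values.

    Every replicate of the focal cell type has PSI exactly ``focal_psi`` and
    every other replicate exactly ``other_psi`` (counts are exact fractions
    of ``depth``, no noise, no clipping) — the construction behind the
    ±(N−1) bound and null-index checks.  ``psi_by_cell`` overrides the
    focal/other pattern with one exact PSI per cell type.
    """
    config = SimConfig(n_cell_types=n_cell_types, n_replicates=n_replicates)
    sample_map = _make_sample_map(config)
    cells = config.cell_types
    ev = _event_annotation(as_type, 0, "chrI", strand, 10_000)
    annotations = {ev.event_id: ev}
    rep = 0 if _representative_is_first(ev) else ev.n_subjunctions - 1
    data = {}
    for sample, cell in zip(sample_map.sample_ids, sample_map.frame["cell_type"]):
        if psi_by_cell is not None:
            psi = float(psi_by_cell[cells.index(cell)])
        else:
            psi = focal_psi if cell == cells[focal_index] else other_psi
        incl = int(round(psi * depth))
        col = [0] * ev.n_subjunctions
        col[rep] = incl
        col[(rep + 1) % ev.n_subjunctions] = depth - incl
        data[sample] = col
    counts = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(
            [(ev.event_id, j) for j in range(ev.n_subjunctions)],
            names=["event_id", "subjunction_index"],
        ),
        dtype=np.int64,
    )
    return counts, annotations, sample_map


def truth_eval(
    ranked: list[UniquenessRecord],
    truth: pd.DataFrame,
    k: int,
) -> tuple[float, pd.DataFrame]:
    """Precision@k and ranks of the planted features in a ranked record list.

    A record is a hit when its (feature_id, focal_cell) matches a planted
    row.  Raises when planted features are absent from the record universe.
    """
    planted = set(zip(truth["feature_id"], truth["focal_cell"]))
    record_features = {r.feature_id for r in ranked}
    missing = {f for f, _ in planted} - record_features
    if missing:
        raise SpliceUniqError(f"planted features absent from ranking: {sorted(missing)[:5]}")
    hits_at_k = sum(
        1 for r in ranked[:k] if (r.feature_id, r.focal_cell) in planted
    )
    positions = {}
    for pos, r in enumerate(ranked, start=1):
        key = (r.feature_id, r.focal_cell)
        if key in planted and key not in positions:
            positions[key] = pos
    ranks = pd.DataFrame(
        [{"feature_id": f, "focal_cell": c, "rank": positions.get((f, c))}
         for f, c in sorted(planted)],
    )
    return hits_at_k / k if k else 0.0, ranks
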