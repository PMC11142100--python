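"""From junction counts to per-sample PSI, plus detection and event filters.

An event's PSI in a sample is the usage fraction of its *representative*
sub-junction: the inclusion (retention) junction for cassette exons and
retained introns, the transcript-upstream junction for alternative 5'/3'
splice sites and mutually exclusive exons (resolved from genomic coordinates
and strand), and the most-upstream-by-coordinate junction for composite
events.  A sample is missing (undetected) for an event when its total
junction reads fall below ``junction_min_reads``; a cell type detects an
event when at least n−1 of its n replicates are non-missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DEFAULT_THRESHOLDS, Thresholds
from .types import Annotations, EventAnnotation, PsiTable, SampleMap, SpliceUniqError


def select_representative_junction(event: EventAnnotation) -> int:
    """Index of the sub-junction whose usage defines the event's PSI."""
    if event.as_type in ("CASSETTE", "IR"):
        if event.inclusion_index is None:
            raise SpliceUniqError(
                f"{event.event_id}: {event.as_type} event has no inclusion junction flagged"
            )
        return event.inclusion_index
    order = event.subjunction_order()
    if event.as_type in ("A5S", "A3S", "MXE"):
        # upstream in transcript orientation: smallest genomic coordinate on
        # the + strand, largest on the − strand
        return order[0] if event.strand == "+" else order[-1]
    # COMPOSITE: the first (smallest genomic start) sub-junction
    return order[0]


def first_junction_index(event: EventAnnotation) -> int:
    """Index of the "first" sub-junction: smallest genomic start (ties: end)."""
    return event.first_junction()


def compute_psi(
    counts: pd.DataFrame,
    annotations: Annotations,
    sample_map: SampleMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> PsiTable:
    """Normalize junction counts into per-sample usage fractions.

    usage(j) = reads(j) / Σ_j' reads(j') within each (event, sample); the
    whole (event, sample) is marked missing when the denominator is below
    ``thresholds.junction_min_reads``.
    """
    event_ids = counts.index.get_level_values(0)
    unknown = set(event_ids) - set(annotations)
    if unknown:
        raise SpliceUniqError(f"events in counts without annotation: {sorted(unknown)[:5]}")
    samples = [s for s in sample_map.sample_ids if s in counts.columns]
    if not samples:
        raise SpliceUniqError("no sample-map samples present in count table")

    values = counts[samples].to_numpy(dtype=float)
    totals = counts[samples].groupby(level=0, sort=False).transform("sum").to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = values / totals
    usage[totals < thresholds.junction_min_reads] = np.nan
    subusage = pd.DataFrame(usage, index=counts.index, columns=samples)

    psi_rows = {}
    for event_id, ev in annotations.items():
        if event_id not in counts.index.get_level_values(0):
            continue
        rep = select_representative_junction(ev)
        try:
            psi_rows[event_id] = subusage.loc[(event_id, rep)]
        except KeyError:
            raise SpliceUniqError(
                f"{event_id}: representative sub-junction {rep} absent from counts"
            ) from None
    psi = pd.DataFrame(psi_rows).T
    psi.index.name = "event_id"
    psi.columns = pd.Index(samples)
    return PsiTable(psi=psi, sample_map=sample_map, subusage=subusage)


def detection_filter(psi: PsiTable, cell_type: str) -> set[str]:
    """Events detected in a cell type: non-missing in ≥ n−1 of n replicates."""
    samples = psi.sample_map.samples_for(cell_type)  # raises on unknown cell
    present = [s for s in samples if s in psi.psi.columns]
    n = len(samples)
    observed = psi.psi[present].notna().sum(axis=1)
    detected = observed[observed >= max(n - 1, 1)]
    return set(detected.index)


def detection_matrix(psi: PsiTable) -> pd.DataFrame:
    """Events × cell types boolean matrix of the (n−1)-replicate detection rule."""
    cols = {}
    for cell in psi.sample_map.cell_types:
        samples = psi.sample_map.samples_for(cell)
        present = [s for s in samples if s in psi.psi.columns]
        n = len(samples)
        cols[cell] = psi.psi[present].notna().sum(axis=1) >= max(n - 1, 1)
    return pd.DataFrame(cols)


def cell_mean_psi(psi: PsiTable) -> pd.DataFrame:
    """Events × cell types replicate-mean PSI (NaN-aware; no detection gate)."""
    cols = {}
    for cell in psi.sample_map.cell_types:
        samples = [s for s in psi.sample_map.samples_for(cell) if s in psi.psi.columns]
        cols[cell] = psi.psi[samples].mean(axis=1)
    return pd.DataFrame(cols)


def classify_alternative(
    psi: PsiTable, low: float = 0.10, high: float = 0.90
) -> set[str]:
    """Events whose mean PSI within ≥1 cell type lies in [low, high] (inclusive).

    Constitutively spliced events (PSI near 0 or 1 everywhere) are excluded;
    the 10–90% band defines "alternative" splicing.
    """
    means = cell_mean_psi(psi)
    in_band = (means >= low) & (means <= high)
    return set(means.index[in_band.any(axis=1)])


def filter_multi_coordinate(annotations: Annotations) -> Annotations:
    """Drop A3S/A5S events with more than two alternative splice-site
    coordinates (>2 sub-junctions); all other classes pass through."""
    return {
        eid: ev
        for eid, ev in annotations.items()
        if not (ev.as_type in ("A3S", "A5S") and ev.n_subjunctions > 2)
    }
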