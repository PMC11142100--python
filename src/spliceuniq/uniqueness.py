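"""The uniqueness index: signed aggregation of cell-specific regulation.

For a focal cell type and a splicing event, the index is the sum — over the
focal cell's comparisons against every other cell type — of the significant
first ΔPSIs (the ΔPSI of the event's most upstream-by-coordinate
sub-junction), orientation-corrected so the sign convention is consistent
across strands: the ΔPSI of A3S events on the + strand and of A5S events on
the − strand is negated before summation.  Non-significant and undetected
comparisons contribute exactly 0, so with N cell types the index is bounded
by ±(N−1) in fractional PSI units.  The expression variant sums significant
log2 fold changes (p < 0.01, |log2FC| > 2) in the same way.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DEFAULT_THRESHOLDS, Thresholds
from .pairwise import two_group_test
from .types import (
    Annotations,
    ComparisonResult,
    ComparisonSet,
    EventAnnotation,
    ExpressionResult,
    SampleMap,
    SpliceUniqError,
    UniquenessRecord,
)


def orientation_sign(as_type: str, strand: str) -> int:
    """−1 for A3S on + strand and A5S on − strand; +1 otherwise.

    These are the classes where the most-upstream *genomic* coordinate does
    not correspond to the same splice-site choice in transcript orientation,
    so their first ΔPSI is reversed during summation.
    """
    if (as_type == "A3S" and strand == "+") or (as_type == "A5S" and strand == "-"):
        return -1
    return 1


def first_delta_psi(result: ComparisonResult, event: EventAnnotation) -> float:
    """Orientation-corrected first ΔPSI of one comparison result."""
    if result.event_id != event.event_id:
        raise SpliceUniqError(
            f"comparison is for {result.event_id!r}, annotation is {event.event_id!r}"
        )
    return orientation_sign(event.as_type, event.strand) * result.delta_psi_first


def _oriented_frame(comparisons: ComparisonSet, annotations: Annotations) -> pd.DataFrame:
    frame = comparisons.frame
    missing = set(frame["event_id"].unique()) - set(annotations)
    if missing:
        raise SpliceUniqError(f"events without annotation: {sorted(missing)[:5]}")
    signs = frame["event_id"].map(
        lambda e: orientation_sign(annotations[e].as_type, annotations[e].strand)
    )
    out = frame.copy()
    out["oriented_first"] = out["delta_psi_first"] * signs
    return out


def uniqueness_index(
    comparisons: ComparisonSet,
    annotations: Annotations,
    feature: str,
    focal_cell: str,
) -> UniquenessRecord:
    """Uniqueness index of one event in one focal cell type."""
    if focal_cell not in comparisons.cell_types:
        raise SpliceUniqError(f"focal cell {focal_cell!r} absent from comparison set")
    if feature not in annotations:
        raise SpliceUniqError(f"event {feature!r} not in annotations")
    frame = comparisons.frame
    rows = frame[(frame["event_id"] == feature) & (frame["cell_a"] == focal_cell)]
    sign = orientation_sign(annotations[feature].as_type, annotations[feature].strand)
    sig = rows["significant"].to_numpy(dtype=bool)
    oriented = sign * rows["delta_psi_first"].to_numpy(dtype=float)
    index = float(oriented[sig].sum()) if sig.any() else 0.0
    return UniquenessRecord(
        feature_id=feature, focal_cell=focal_cell, index=index,
        n_significant=int(sig.sum()), n_compared=len(rows),
        feature_type=annotations[feature].as_type,
    )


def uniqueness_table(
    comparisons: ComparisonSet,
    annotations: Annotations,
    as_type: str | None = None,
) -> list[UniquenessRecord]:
    """Uniqueness records for every (event, cell type) combination.

    Combinations with no comparisons (undetected everywhere) get index 0
    with n_compared 0, so every event × cell slot is present.
    """
    frame = _oriented_frame(comparisons, annotations)
    if as_type is not None:
        frame = frame[frame["as_type"] == as_type]
        event_universe = [e for e in annotations if annotations[e].as_type == as_type]
    else:
        event_universe = list(annotations)
    contrib = frame["oriented_first"].where(frame["significant"], 0.0)
    grouped = (
        frame.assign(_contrib=contrib)
        .groupby(["event_id", "cell_a"], sort=False)
        .agg(
            index=("_contrib", "sum"),
            n_significant=("significant", "sum"),
            n_compared=("significant", "size"),
        )
    )
    records = []
    cells = comparisons.cell_types
    for eid in event_universe:
        ftype = annotations[eid].as_type
        for cell in cells:
            if (eid, cell) in grouped.index:
                row = grouped.loc[(eid, cell)]
                n_sig = int(row["n_significant"])
                records.append(UniquenessRecord(
                    feature_id=eid, focal_cell=cell,
                    index=float(row["index"]) if n_sig else 0.0,
                    n_significant=n_sig, n_compared=int(row["n_compared"]),
                    feature_type=ftype,
                ))
            else:
                records.append(UniquenessRecord(
                    feature_id=eid, focal_cell=cell, index=0.0,
                    n_significant=0, n_compared=0, feature_type=ftype,
                ))
    return records


def sort_uniqueness(
    records: list[UniquenessRecord], descending: bool = True
) -> list[UniquenessRecord]:
    """Sort by index (descending = most "uniquely up/upstream" first).

    Deterministic tie-break: |index| descending, then feature_id ascending,
    then focal cell ascending.
    """
    return sorted(
        records,
        key=lambda r: (
            -r.index if descending else r.index,
            -abs(r.index),
            r.feature_id,
            r.focal_cell,
        ),
    )


def rank_by_magnitude(records: list[UniquenessRecord]) -> list[UniquenessRecord]:
    """Rank records by |index| descending (tie: feature_id, focal cell)."""
    return sorted(records, key=lambda r: (-abs(r.index), r.feature_id, r.focal_cell))


# ---------------------------------------------------------------------------
# gene-expression variant

def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization of a genes × samples count table."""
    lib = counts.sum(axis=0)
    zero = lib[lib == 0].index.tolist()
    if zero:
        raise SpliceUniqError(f"zero library size for samples: {zero}")
    return counts / lib * 1e6


def expression_pair_test(
    counts_a,
    counts_b,
    lib_a=None,
    lib_b=None,
    gene_id: str = "",
    cell_a: str = "",
    cell_b: str = "",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> ExpressionResult:
    """Two-group expression test for one gene.

    ``counts_a``/``counts_b`` are per-replicate counts; ``lib_a``/``lib_b``
    the matching library sizes (omit if the counts are already CPM).
    log2FC = log2((mean CPM_a + 1) / (mean CPM_b + 1)); p from the same
    two-group location test as splicing, applied to log2(CPM + 1).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if lib_a is not None:
        lib_a = np.asarray(lib_a, dtype=float)
        if (lib_a == 0).any():
            raise SpliceUniqError("zero library size")
        a = a / lib_a * 1e6
    if lib_b is not None:
        lib_b = np.asarray(lib_b, dtype=float)
        if (lib_b == 0).any():
            raise SpliceUniqError("zero library size")
        b = b / lib_b * 1e6
    lfc = float(np.log2((a.mean() + 1.0) / (b.mean() + 1.0)))
    p = two_group_test(np.log2(a + 1.0), np.log2(b + 1.0))
    significant = (p < thresholds.expr_p_max) and (abs(lfc) > thresholds.expr_lfc_min)
    return ExpressionResult(
        gene_id=gene_id, cell_a=cell_a, cell_b=cell_b,
        log2_fold_change=lfc, p_value=p, significant=significant,
    )


def expression_all_pairs(
    counts: pd.DataFrame,
    sample_map: SampleMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Differential expression for all ordered cell pairs (vectorized).

    Returns a DataFrame with columns gene_id, cell_a, cell_b,
    log2_fold_change, p_value, significant.  Each unordered pair is tested
    once and mirrored, making log2FC antisymmetry exact.
    """
    log_cpm = np.log2(cpm(counts) + 1.0)
    mean_cpm = {}
    log_vals = {}
    cells = sample_map.cell_types
    cpm_frame = cpm(counts)
    for cell in cells:
        samples = [s for s in sample_map.samples_for(cell) if s in counts.columns]
        if not samples:
            raise SpliceUniqError(f"cell type {cell!r} has no samples in count table")
        mean_cpm[cell] = cpm_frame[samples].mean(axis=1).to_numpy()
        log_vals[cell] = log_cpm[samples].to_numpy()
    genes = counts.index.to_numpy(dtype=object)
    rows = []
    from .pairwise import _pair_pvalues  # shared batch test machinery
    for i, cell_a in enumerate(cells):
        for cell_b in cells[i + 1:]:
            lfc = np.log2((mean_cpm[cell_a] + 1.0) / (mean_cpm[cell_b] + 1.0))
            p = _pair_pvalues(log_vals[cell_a], log_vals[cell_b])
            sig = (p < thresholds.expr_p_max) & (np.abs(lfc) > thresholds.expr_lfc_min)
            for ca, cb, f in ((cell_a, cell_b, lfc), (cell_b, cell_a, -lfc)):
                rows.append(pd.DataFrame({
                    "gene_id": genes, "cell_a": ca, "cell_b": cb,
                    "log2_fold_change": f, "p_value": p, "significant": sig,
                }))
    return pd.concat(rows, ignore_index=True)


def expression_uniqueness(
    expr_results: pd.DataFrame,
    gene: str,
    focal_cell: str,
) -> UniquenessRecord:
    """Expression uniqueness index: sum of significant log2FC (focal vs all)."""
    if gene not in set(expr_results["gene_id"]):
        raise SpliceUniqError(f"gene {gene!r} absent from expression results")
    rows = expr_results[
        (expr_results["gene_id"] == gene) & (expr_results["cell_a"] == focal_cell)
    ]
    sig = rows["significant"].to_numpy(dtype=bool)
    lfc = rows["log2_fold_change"].to_numpy(dtype=float)
    return UniquenessRecord(
        feature_id=gene, focal_cell=focal_cell,
        index=float(lfc[sig].sum()) if sig.any() else 0.0,
        n_significant=int(sig.sum()), n_compared=len(rows),
        feature_type="expression",
    )


def expression_uniqueness_table(
    expr_results: pd.DataFrame,
    genes: list[str] | None = None,
) -> list[UniquenessRecord]:
    """Expression uniqueness records for every (gene, cell); ``genes``
    optionally restricts to a subset (e.g. an RNA-binding-protein list)."""
    frame = expr_results
    if genes is not None:
        frame = frame[frame["gene_id"].isin(set(genes))]
    contrib = frame["log2_fold_change"].where(frame["significant"], 0.0)
    grouped = (
        frame.assign(_contrib=contrib)
        .groupby(["gene_id", "cell_a"], sort=False)
        .agg(
            index=("_contrib", "sum"),
            n_significant=("significant", "sum"),
            n_compared=("significant", "size"),
        )
    )
    records = []
    for (gene, cell), row in grouped.iterrows():
        n_sig = int(row["n_significant"])
        records.append(UniquenessRecord(
            feature_id=gene, focal_cell=cell,
            index=float(row["index"]) if n_sig else 0.0,
            n_significant=n_sig, n_compared=int(row["n_compared"]),
            feature_type="expression",
        ))
    return records
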