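"""Global summaries: per-pair count matrices, class totals, correlations,
outlier cells, directional bias, and replicate-averaged usage mega matrices.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_THRESHOLDS, Thresholds
from .events import detection_matrix
from .types import (
    Annotations,
    ComparisonSet,
    PsiTable,
    SpliceUniqError,
    UniquenessRecord,
)


def count_differential(comparisons: ComparisonSet) -> pd.DataFrame:
    """Significant-event counts per (as_type, cell_a, cell_b).

    Every ordered pair appears for every AS type present, with 0 when no
    event was called; a single call counts as 1 (each event can be detected
    at most once within one comparison).
    """
    frame = comparisons.frame
    as_types = sorted(frame["as_type"].unique())
    pairs = [(a, b) for a in comparisons.cell_types for b in comparisons.cell_types if a != b]
    counts = (
        frame[frame["significant"]]
        .groupby(["as_type", "cell_a", "cell_b"])
        .size()
    )
    full_index = pd.MultiIndex.from_tuples(
        [(t, a, b) for t in as_types for a, b in pairs],
        names=["as_type", "cell_a", "cell_b"],
    )
    out = counts.reindex(full_index, fill_value=0).astype(int)
    return out.rename("n_significant").reset_index()


def global_totals(
    comparisons: ComparisonSet,
    annotations: Annotations,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    alternative_events: set[str] | None = None,
) -> pd.DataFrame:
    """Per-AS-type totals of differential events and genes.

    An event (and its gene) enters the global totals only when it is called
    significant in at least ``global_min_comparisons`` pairwise comparisons
    (counted over ordered comparisons); per-pair heatmap counts keep the
    single-count threshold instead (see :func:`count_differential`).
    """
    frame = comparisons.frame
    sig = frame[frame["significant"]]
    calls = sig.groupby(["as_type", "event_id"]).size()
    keep = calls[calls >= thresholds.global_min_comparisons]
    rows = []
    for as_type in sorted(frame["as_type"].unique()):
        if as_type in keep.index.get_level_values(0):
            events = keep.loc[as_type].index.tolist()
        else:
            events = []
        genes = sorted({annotations[e].gene_id for e in events if e in annotations})
        row = {
            "as_type": as_type,
            "n_differential_events": len(events),
            "n_differential_genes": len(genes),
        }
        if alternative_events is not None:
            row["n_alternative_events"] = sum(
                1 for e, ann in annotations.items()
                if ann.as_type == as_type and e in alternative_events
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    total = out["n_differential_events"].sum()
    out["fraction_of_differential"] = (
        out["n_differential_events"] / total if total else 0.0
    )
    return out


def _adjusted_r2(x: np.ndarray, y: np.ndarray) -> float:
    m = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("degenerate (constant) count vector; adjusted R^2 reported as 0")
        return 0.0
    r = stats.linregress(x, y).rvalue
    r2 = r * r
    return 1.0 - (1.0 - r2) * (m - 1) / (m - 2)


def splice_type_correlation(
    counts: pd.DataFrame,
    expr_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Adjusted R² between per-comparison counts of each regulatory category.

    ``counts`` is the output of :func:`count_differential`; ``expr_counts``
    optionally adds an "expression" category from a like-shaped table of
    per-pair significant gene counts.  Each unordered cell pair contributes
    one observation (the ordered duplicates are antisymmetric copies).
    """
    def pivot(frame: pd.DataFrame) -> pd.DataFrame:
        sub = frame[frame["cell_a"] < frame["cell_b"]]
        return sub.pivot_table(
            index=["cell_a", "cell_b"], columns="as_type",
            values="n_significant", fill_value=0,
        )

    table = pivot(counts)
    if expr_counts is not None:
        expr = pivot(expr_counts)
        expr.columns = ["expression" for _ in expr.columns]
        table = table.join(expr, how="outer").fillna(0)
    if len(table) < 3:
        raise SpliceUniqError("need >=3 pair observations per regression")
    categories = list(table.columns)
    out = pd.DataFrame(index=categories, columns=categories, dtype=float)
    for i, ci in enumerate(categories):
        for cj in categories[i:]:
            value = 1.0 if ci == cj else _adjusted_r2(
                table[ci].to_numpy(dtype=float), table[cj].to_numpy(dtype=float)
            )
            out.loc[ci, cj] = value
            out.loc[cj, ci] = value
    return out


def outlier_cells(counts: pd.DataFrame, as_type: str) -> pd.DataFrame:
    """Per-cell totals of significant events for one AS type, with robust
    z-scores: z = (total − median) / MAD, flagged at |z| > 3.5."""
    sub = counts[counts["as_type"] == as_type]
    if sub.empty:
        raise SpliceUniqError(f"no counts for AS type {as_type!r}")
    totals = sub.groupby("cell_a")["n_significant"].sum().sort_index()
    x = totals.to_numpy(dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        diff = x - med
        z = np.zeros_like(x)
        z[diff != 0] = np.sign(diff[diff != 0]) * np.inf
    else:
        z = (x - med) / mad
    return pd.DataFrame({
        "cell_type": totals.index,
        "total_significant": totals.to_numpy(dtype=int),
        "robust_z": z,
        "outlier": np.abs(z) > 3.5,
    }).reset_index(drop=True)


def directional_bias(
    uniq: list[UniquenessRecord],
    focal_cell: str,
    as_type: str | None = None,
) -> float | None:
    """Fraction of a cell's nonzero-index events with a positive index.

    Positive means upstream/included usage after orientation correction.
    Returns ``None`` (undefined) when the cell has no nonzero records.
    """
    relevant = [
        r for r in uniq
        if r.focal_cell == focal_cell and r.index != 0.0
        and (as_type is None or r.feature_type == as_type)
    ]
    if not relevant:
        return None
    return sum(1 for r in relevant if r.index > 0) / len(relevant)


def usage_mega_matrix(
    psi: PsiTable, annotations: Annotations
) -> dict[str, pd.DataFrame]:
    """Replicate-averaged representative-junction usage, one event × cell
    matrix per AS type ("mega matrix").  A cell entry is missing unless the
    event passes the (n−1) detection rule in that cell."""
    detected = detection_matrix(psi)
    cols = {}
    for cell in psi.sample_map.cell_types:
        samples = [s for s in psi.sample_map.samples_for(cell) if s in psi.psi.columns]
        means = psi.psi[samples].mean(axis=1)
        cols[cell] = means.where(detected[cell])
    merged = pd.DataFrame(cols)
    out: dict[str, pd.DataFrame] = {}
    for as_type in sorted({ev.as_type for ev in annotations.values()}):
        events = [e for e, ev in annotations.items()
                  if ev.as_type == as_type and e in merged.index]
        matrix = merged.loc[events]
        out[as_type] = matrix[matrix.notna().any(axis=1)]
    return out
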