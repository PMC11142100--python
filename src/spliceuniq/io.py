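"""Readers and writers for every external table the pipeline touches.

All files are TSV.  Writers are deterministic: fixed column order, fixed
float formatting, sorted where no natural order exists — identical inputs
produce byte-identical files.  PSI values are fractions internally and in
the PSI table on disk; the VISTA export displays percent (0–100, one
decimal).  Missing (undetected) PSI is an empty field, never 0.
"""

from __future__ import annotations

import difflib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    Annotations,
    ComparisonSet,
    EventAnnotation,
    PsiTable,
    SampleMap,
    SpliceUniqError,
    UniquenessRecord,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6f"


# ---------------------------------------------------------------------------
# sample map

def read_sample_map(path: str | Path) -> SampleMap:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_type": str})
    return SampleMap(frame)


def write_sample_map(sample_map: SampleMap, path: str | Path) -> None:
    sample_map.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# event annotations (BED-like TSV)

_ANNOT_HEADER = (
    "# spliceuniq event annotations; coordinates are 0-based half-open (BED convention); "
    "sub-junction lists are comma-separated\n"
)
_ANNOT_COLUMNS = [
    "chrom", "chromStart", "chromEnd", "event_id", "score", "strand",
    "gene_id", "as_type", "subjunction_starts", "subjunction_ends", "inclusion_index",
]


def write_annotations(annotations: Annotations, path: str | Path) -> None:
    """Write annotations as a BED-like TSV (0-based half-open on disk)."""
    rows = []
    for ev in annotations.values():
        starts0 = [s - 1 for s in ev.starts]  # 1-based inclusive -> 0-based half-open
        rows.append({
            "chrom": ev.chrom,
            "chromStart": min(starts0),
            "chromEnd": max(ev.ends),
            "event_id": ev.event_id,
            "score": 0,
            "strand": ev.strand,
            "gene_id": ev.gene_id,
            "as_type": ev.as_type,
            "subjunction_starts": ",".join(str(s) for s in starts0),
            "subjunction_ends": ",".join(str(e) for e in ev.ends),
            "inclusion_index": "" if ev.inclusion_index is None else str(ev.inclusion_index),
        })
    frame = pd.DataFrame(rows, columns=_ANNOT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_ANNOT_HEADER)
        frame.to_csv(fh, sep="\t", index=False)


def read_annotations(path: str | Path) -> Annotations:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _ANNOT_COLUMNS if c not in frame.columns]
    if missing:
        raise SpliceUniqError(f"annotation file {path} missing columns: {missing}")
    annotations: Annotations = {}
    for row in frame.itertuples(index=False):
        starts = tuple(int(s) + 1 for s in row.subjunction_starts.split(","))
        ends = tuple(int(e) for e in row.subjunction_ends.split(","))
        inclusion = None
        if isinstance(row.inclusion_index, str) and row.inclusion_index != "":
            inclusion = int(row.inclusion_index)
        ev = EventAnnotation(
            event_id=row.event_id, gene_id=row.gene_id, chrom=row.chrom,
            strand=row.strand, as_type=row.as_type,
            starts=starts, ends=ends, inclusion_index=inclusion,
        )
        if ev.event_id in annotations:
            raise SpliceUniqError(f"duplicate event_id {ev.event_id!r} in {path}")
        annotations[ev.event_id] = ev
    return annotations


# ---------------------------------------------------------------------------
# junction counts

def read_junction_counts(path: str | Path, sample_map: SampleMap) -> pd.DataFrame:
    """Read a per-replicate junction count table.

    Expected columns: ``event_id``, ``subjunction_index``, then one column
    per sample.  Returns a DataFrame indexed by (event_id, subjunction_index)
    with one integer column per sample; cells missing from the file are
    treated as 0 with a logged warning.
    """
    frame = pd.read_csv(path, sep="\t")
    for col in ("event_id", "subjunction_index"):
        if col not in frame.columns:
            raise SpliceUniqError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in frame.columns if c not in ("event_id", "subjunction_index")]
    known = set(sample_map.sample_ids)
    for col in sample_cols:
        if col not in known:
            raise SpliceUniqError(
                f"{path}: sample column {col!r} is not in the sample map"
            )
    table = frame.set_index(["event_id", "subjunction_index"])[sample_cols]
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].tolist()
        raise SpliceUniqError(f"{path}: duplicate (event, sub-junction) rows: {dupes[:5]}")
    if table.isna().any().any():
        n_missing = int(table.isna().sum().sum())
        logger.warning("%s: %d missing count cells treated as 0", path, n_missing)
        table = table.fillna(0)
    values = table.to_numpy(dtype=float)
    bad = ~np.isfinite(values) | (values < 0) | (values != np.round(values))
    if bad.any():
        row_pos = int(np.argwhere(bad)[0][0])
        raise SpliceUniqError(
            f"{path}: negative or non-integer count at data row {row_pos + 1} "
            f"(event {table.index[row_pos][0]})"
        )
    return table.astype(np.int64)


def write_junction_counts(counts: pd.DataFrame, path: str | Path) -> None:
    out = counts.reset_index()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PSI tables

def read_psi_table(path: str | Path, sample_map: SampleMap | None = None) -> PsiTable:
    """Read an event × sample PSI table; empty cells are missing (undetected)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise SpliceUniqError(
            f"{path}: PSI value {values[i, j]} outside [0, 1] "
            f"(event {frame.index[i]}, sample {frame.columns[j]})"
        )
    if sample_map is None:
        sample_map = SampleMap(pd.DataFrame({
            "sample_id": list(frame.columns),
            "cell_type": list(frame.columns),
            "replicate_index": 1,
        }))
    return PsiTable(psi=frame.astype(float), sample_map=sample_map)


def write_psi_table(psi: PsiTable, path: str | Path) -> None:
    psi.psi.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="event_id")


def write_subusage_table(psi: PsiTable, path: str | Path) -> None:
    if psi.subusage is None:
        raise SpliceUniqError("PsiTable has no sub-junction usage to write")
    psi.subusage.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# comparisons

def write_comparisons(comparisons: ComparisonSet, path: str | Path) -> None:
    out = comparisons.frame.copy()
    for col in ("delta_psi", "delta_psi_first", "p_value", "q_value"):
        out[col] = out[col].map(lambda v: _FLOAT_FMT % v)
    out["significant"] = out["significant"].map({True: "1", False: "0"})
    out.to_csv(path, sep="\t", index=False)


def read_comparisons(path: str | Path) -> ComparisonSet:
    frame = pd.read_csv(path, sep="\t")
    frame["significant"] = frame["significant"].astype(bool)
    return ComparisonSet(frame)


# ---------------------------------------------------------------------------
# uniqueness / generic results

def write_results_tsv(records: list[UniquenessRecord], path: str | Path) -> None:
    """Write uniqueness records (splicing or expression) as TSV."""
    rows = [{
        "feature_type": r.feature_type,
        "feature_id": r.feature_id,
        "focal_cell": r.focal_cell,
        "index": _FLOAT_FMT % r.index,
        "n_significant": r.n_significant,
        "n_compared": r.n_compared,
    } for r in records]
    cols = ["feature_type", "feature_id", "focal_cell", "index", "n_significant", "n_compared"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> list[UniquenessRecord]:
    frame = pd.read_csv(path, sep="\t")
    return [
        UniquenessRecord(
            feature_id=row.feature_id, focal_cell=row.focal_cell,
            index=float(row.index_), n_significant=int(row.n_significant),
            n_compared=int(row.n_compared), feature_type=row.feature_type,
        )
        for row in frame.rename(columns={"index": "index_"}).itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# VISTA-style spatial export

def export_vista_table(
    usage: dict[str, pd.DataFrame],
    event_id: str,
    path: str | Path,
    sample_map: SampleMap,
) -> None:
    """Export one event's per-cell inclusion levels for a spatial heatmap.

    ``usage`` maps AS type → (event × cell type) replicate-mean usage matrix.
    Output columns: cell_type, percent_spliced_in (0–100 scale, one decimal),
    n_replicates.  Cell types where the event is undetected are omitted.
    """
    if not usage or all(m.empty for m in usage.values()):
        raise SpliceUniqError("usage matrix is empty")
    row = None
    for matrix in usage.values():
        if event_id in matrix.index:
            row = matrix.loc[event_id]
            break
    if row is None:
        all_ids = sorted({i for m in usage.values() for i in m.index})
        near = difflib.get_close_matches(event_id, all_ids, n=3, cutoff=0.0)
        raise SpliceUniqError(f"unknown event_id {event_id!r}; nearest: {near}")
    rows = []
    for cell in row.index:
        value = row[cell]
        if pd.isna(value):
            continue
        rows.append({
            "cell_type": cell,
            "percent_spliced_in": "%.1f" % (100.0 * float(value)),
            "n_replicates": sample_map.n_replicates(cell),
        })
    cols = ["cell_type", "percent_spliced_in", "n_replicates"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
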