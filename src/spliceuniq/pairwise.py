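"""Differential splicing for every ordered pair of cell types.

For each pair and each event detected in both cell types, replicate PSI
values are compared with a two-group location test: a Welch t-test whenever
both groups carry ≥2 replicates, an exact permutation test on the
difference of means when a group is down to a single replicate (where Welch
is undefined), and a deterministic rule when both groups have zero variance
(p = 0 if the means differ, p = 1 if equal).  Welch is the primary test
because the downstream Benjamini–Hochberg correction runs within small
(cell pair × AS type) families: an exact permutation p at 4v4 replicates is
bounded below by 2/70 ≈ 0.029, which can never survive BH in a family of
tens of events, whereas the continuous Welch p can.  The permutation test
remains available via ``method="permutation"``.  An event is called
significant when |ΔPSI| > 0.10 and p < 0.05 and q < 0.05.

Each unordered pair is computed once and mirrored into both ordered
directions, which makes the antisymmetry ΔPSI(A,B) = −ΔPSI(B,A) exact; the
resulting ComparisonSet still enumerates all N·(N−1) ordered pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_THRESHOLDS, Thresholds
from .events import first_junction_index, select_representative_junction
from .types import (
    Annotations,
    ComparisonResult,
    ComparisonSet,
    PsiTable,
    SpliceUniqError,
)

_PERMUTATION_MAX_TOTAL = 16  # C(16, 8) = 12870 relabelings; enough for 8v8
_TIE_EPS = 1e-12


def ordered_pairs(cell_types: list[str]) -> list[tuple[str, str]]:
    """All N·(N−1) ordered (cell_a, cell_b) pairs, in deterministic order."""
    return [(a, b) for a in cell_types for b in cell_types if a != b]


@lru_cache(maxsize=None)
def _perm_weights(n_a: int, n_b: int) -> np.ndarray:
    """Mean-difference weight matrix over all C(n_a+n_b, n_a) relabelings.

    Row r dotted with the pooled value vector gives mean(group_a) −
    mean(group_b) under relabeling r; row 0 is the observed labeling.
    """
    n = n_a + n_b
    combos = list(itertools.combinations(range(n), n_a))
    weights = np.full((len(combos), n), -1.0 / n_b)
    for r, combo in enumerate(combos):
        weights[r, list(combo)] = 1.0 / n_a
    return weights


def _permutation_pvalues(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Exact two-sided permutation p-values, rows = events (no NaNs)."""
    weights = _perm_weights(values_a.shape[1], values_b.shape[1])
    pooled = np.concatenate([values_a, values_b], axis=1)
    diffs = pooled @ weights.T
    observed = np.abs(diffs[:, [0]])
    return np.mean(np.abs(diffs) >= observed - _TIE_EPS, axis=1)


def _welch_pvalues(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical groups trigger scipy's catastrophic-cancellation
        # warning; those rows are overridden by the zero-variance rule
        warnings.simplefilter("ignore", RuntimeWarning)
        result = stats.ttest_ind(values_a, values_b, axis=1, equal_var=False)
    p = np.asarray(result.pvalue, dtype=float)
    return np.where(np.isfinite(p), p, 1.0)


def two_group_test(psis_a, psis_b, method: str = "auto") -> float:
    """Two-group location test on replicate PSI (or any bounded) values.

    NaNs are dropped.  Zero variance in both groups short-circuits to the
    deterministic rule.  ``method``: "auto" (Welch when both groups have ≥2
    replicates, exact permutation otherwise), "welch", or "permutation"
    (all C(n_a+n_b, n_a) relabelings; pooled n capped at 16).
    """
    a = np.asarray(psis_a, dtype=float)
    b = np.asarray(psis_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise SpliceUniqError("two_group_test: empty group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.0 if a[0] != b[0] else 1.0
    if method == "auto":
        method = "welch" if min(a.size, b.size) >= 2 else "permutation"
    if method == "permutation":
        if a.size + b.size > _PERMUTATION_MAX_TOTAL:
            raise SpliceUniqError(
                f"permutation test limited to pooled n <= {_PERMUTATION_MAX_TOTAL}"
            )
        return float(_permutation_pvalues(a[None, :], b[None, :])[0])
    if method == "welch":
        return float(_welch_pvalues(a[None, :], b[None, :])[0])
    raise SpliceUniqError(f"unknown test method {method!r}")


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# vectorized all-pairs machinery

@dataclass
class _PairwiseContext:
    event_ids: np.ndarray            # object array of event ids
    as_types: np.ndarray             # parallel AS-type labels
    rep_vals: dict[str, np.ndarray]  # cell -> events × replicates PSI
    first_vals: dict[str, np.ndarray]
    detected: dict[str, np.ndarray]  # cell -> events bool
    mean_rep: dict[str, np.ndarray]
    mean_first: dict[str, np.ndarray]
    n_obs: dict[str, np.ndarray]     # cell -> non-missing replicate counts


def first_junction_usage(
    psi: PsiTable, annotations: Annotations, event_ids: list[str]
) -> pd.DataFrame:
    """Per-sample usage of each event's first (smallest-start) sub-junction."""
    if psi.subusage is not None:
        keys = [(eid, first_junction_index(annotations[eid])) for eid in event_ids]
        frame = psi.subusage.reindex(pd.MultiIndex.from_tuples(keys))
        frame.index = pd.Index(event_ids, name="event_id")
        return frame
    # derive from representative-junction PSI for two-junction events
    rows = {}
    for eid in event_ids:
        ev = annotations[eid]
        rep = select_representative_junction(ev)
        first = first_junction_index(ev)
        if first == rep:
            rows[eid] = psi.psi.loc[eid]
        elif ev.n_subjunctions == 2:
            rows[eid] = 1.0 - psi.psi.loc[eid]
        else:
            raise SpliceUniqError(
                f"{eid}: first-junction usage needs the sub-usage table for "
                f"events with {ev.n_subjunctions} sub-junctions"
            )
    return pd.DataFrame(rows).T


def _build_context(
    psi: PsiTable,
    annotations: Annotations,
    events: list[str] | None,
    thresholds: Thresholds,
) -> _PairwiseContext:
    universe = [e for e in psi.psi.index if e in annotations]
    if events is not None:
        wanted = set(events)
        universe = [e for e in universe if e in wanted]
    as_types = np.array([annotations[e].as_type for e in universe], dtype=object)
    rep_frame = psi.psi.loc[universe]
    first_frame = first_junction_usage(psi, annotations, universe)

    ctx = _PairwiseContext(
        event_ids=np.array(universe, dtype=object), as_types=as_types,
        rep_vals={}, first_vals={}, detected={}, mean_rep={}, mean_first={}, n_obs={},
    )
    for cell in psi.sample_map.cell_types:
        samples = [s for s in psi.sample_map.samples_for(cell) if s in psi.psi.columns]
        n = psi.sample_map.n_replicates(cell)
        rep = rep_frame[samples].to_numpy(dtype=float)
        first = first_frame[samples].to_numpy(dtype=float)
        obs = (~np.isnan(rep)).sum(axis=1)
        obs_first = (~np.isnan(first)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_rep = np.nansum(rep, axis=1) / np.where(obs > 0, obs, np.nan)
            mean_first = np.nansum(first, axis=1) / np.where(obs_first > 0, obs_first, np.nan)
        ctx.rep_vals[cell] = rep
        ctx.first_vals[cell] = first
        ctx.detected[cell] = obs >= max(n - 1, 1)
        ctx.mean_rep[cell] = mean_rep
        ctx.mean_first[cell] = mean_first
        ctx.n_obs[cell] = obs
    return ctx


def _pair_pvalues(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Row-wise two-group p-values with NaN handling and zero-variance rule."""
    n_rows = values_a.shape[0]
    p = np.empty(n_rows, dtype=float)
    full = ~(np.isnan(values_a).any(axis=1) | np.isnan(values_b).any(axis=1))
    if full.any():
        va, vb = values_a[full], values_b[full]
        if min(va.shape[1], vb.shape[1]) >= 2:
            p_full = _welch_pvalues(va, vb)
        else:
            p_full = _permutation_pvalues(va, vb)
        const = (np.ptp(va, axis=1) == 0) & (np.ptp(vb, axis=1) == 0)
        if const.any():
            equal = va[:, 0] == vb[:, 0]
            p_full = np.where(const, np.where(equal, 1.0, 0.0), p_full)
        p[full] = p_full
    for i in np.where(~full)[0]:
        p[i] = two_group_test(values_a[i], values_b[i])
    return p


def _pair_arrays(ctx: _PairwiseContext, cell_a: str, cell_b: str, thresholds: Thresholds):
    """Per-event comparison arrays for one unordered pair (a as focal)."""
    both = ctx.detected[cell_a] & ctx.detected[cell_b]
    idx = np.where(both)[0]
    if idx.size == 0:
        return None
    p = _pair_pvalues(ctx.rep_vals[cell_a][idx], ctx.rep_vals[cell_b][idx])
    delta = ctx.mean_rep[cell_a][idx] - ctx.mean_rep[cell_b][idx]
    delta_first = ctx.mean_first[cell_a][idx] - ctx.mean_first[cell_b][idx]
    q = np.empty_like(p)
    as_types = ctx.as_types[idx]
    for t in np.unique(as_types):
        mask = as_types == t
        q[mask] = adjust_fdr(p[mask])
    significant = (
        (np.abs(delta) > thresholds.delta_psi_min)
        & (p < thresholds.p_max)
        & (q < thresholds.q_max)
    )
    return {
        "idx": idx, "as_type": as_types, "event_id": ctx.event_ids[idx],
        "delta": delta, "delta_first": delta_first, "p": p, "q": q,
        "significant": significant,
        "n_a": ctx.n_obs[cell_a][idx], "n_b": ctx.n_obs[cell_b][idx],
    }


def _arrays_to_frame(pair_chunks: list[dict]) -> pd.DataFrame:
    if not pair_chunks:
        return pd.DataFrame()
    return pd.DataFrame({
        "as_type": np.concatenate([c["as_type"] for c in pair_chunks]),
        "event_id": np.concatenate([c["event_id"] for c in pair_chunks]),
        "cell_a": np.concatenate([np.repeat(c["cell_a"], len(c["idx"])) for c in pair_chunks]),
        "cell_b": np.concatenate([np.repeat(c["cell_b"], len(c["idx"])) for c in pair_chunks]),
        "delta_psi": np.concatenate([c["delta"] for c in pair_chunks]),
        "delta_psi_first": np.concatenate([c["delta_first"] for c in pair_chunks]),
        "p_value": np.concatenate([c["p"] for c in pair_chunks]),
        "q_value": np.concatenate([c["q"] for c in pair_chunks]),
        "significant": np.concatenate([c["significant"] for c in pair_chunks]),
        "n_a": np.concatenate([c["n_a"] for c in pair_chunks]),
        "n_b": np.concatenate([c["n_b"] for c in pair_chunks]),
    })


def _mirror_chunk(chunk: dict) -> dict:
    return {
        **chunk,
        "cell_a": chunk["cell_b"], "cell_b": chunk["cell_a"],
        "delta": -chunk["delta"], "delta_first": -chunk["delta_first"],
        "n_a": chunk["n_b"], "n_b": chunk["n_a"],
    }


def compare_pair(
    psi: PsiTable,
    annotations: Annotations,
    cell_a: str,
    cell_b: str,
    events: list[str] | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[ComparisonResult]:
    """Differential splicing for one ordered cell pair.

    Events failing the (n−1) detection rule in either cell are skipped, not
    failed.  q-values are BH within each AS-type family of this pair.
    """
    for cell in (cell_a, cell_b):
        if not psi.sample_map.samples_for(cell):  # raises on unknown cell
            raise SpliceUniqError(f"cell type {cell!r} has no samples")
    ctx = _build_context(psi, annotations, events, thresholds)
    chunk = _pair_arrays(ctx, cell_a, cell_b, thresholds)
    if chunk is None:
        return []
    return [
        ComparisonResult(
            event_id=chunk["event_id"][i], as_type=chunk["as_type"][i],
            cell_a=cell_a, cell_b=cell_b,
            delta_psi=float(chunk["delta"][i]),
            delta_psi_first=float(chunk["delta_first"][i]),
            p_value=float(chunk["p"][i]), q_value=float(chunk["q"][i]),
            significant=bool(chunk["significant"][i]),
            n_a=int(chunk["n_a"][i]), n_b=int(chunk["n_b"][i]),
        )
        for i in range(len(chunk["idx"]))
    ]


def run_all_pairs(
    psi: PsiTable,
    annotations: Annotations,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    events: list[str] | None = None,
) -> ComparisonSet:
    """Differential splicing across all ordered cell-type pairs."""
    cells = psi.sample_map.cell_types
    if len(cells) < 2:
        raise SpliceUniqError("need at least 2 cell types for pairwise comparison")
    ctx = _build_context(psi, annotations, events, thresholds)
    chunks: list[dict] = []
    for i, cell_a in enumerate(cells):
        for cell_b in cells[i + 1:]:
            chunk = _pair_arrays(ctx, cell_a, cell_b, thresholds)
            if chunk is None:
                continue
            chunk = {**chunk, "cell_a": cell_a, "cell_b": cell_b}
            chunks.append(chunk)
            chunks.append(_mirror_chunk(chunk))
    frame = _arrays_to_frame(chunks)
    return ComparisonSet(frame, cell_types=list(cells))
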