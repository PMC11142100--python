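import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spliceuniq import events, pairwise, synthetic
from spliceuniq.types import ComparisonSet, EventAnnotation, SampleMap


@pytest.fixture(scope="session")
def small_sim():
    """A 6-cell, 3-replicate simulated dataset with planted events."""
    config = synthetic.SimConfig(
        n_cell_types=6, n_replicates=3,
        events_per_type={t: 8 for t in synthetic.AS_TYPES},
        planted_fraction=0.10, seed=11,
    )
    counts, annotations, sample_map, truth = synthetic.simulate_splicing(config)
    return counts, annotations, sample_map, truth


@pytest.fixture(scope="session")
def small_psi(small_sim):
    counts, annotations, sample_map, _ = small_sim
    return events.compute_psi(counts, annotations, sample_map)


@pytest.fixture(scope="session")
def small_comparisons(small_sim, small_psi):
    _, annotations, _, _ = small_sim
    return pairwise.run_all_pairs(small_psi, annotations)


@pytest.fixture
def cassette_event():
    return EventAnnotation(
        event_id="ev1", gene_id="g1", chrom="chrI", strand="+",
        as_type="CASSETTE", starts=(100, 100), ends=(200, 400),
        inclusion_index=0,
    )


def make_sample_map(cells: dict[str, int]) -> SampleMap:
    rows = [
        {"sample_id": f"{c}_r{i + 1}", "cell_type": c, "replicate_index": i + 1}
        for c, n in cells.items() for i in range(n)
    ]
    return SampleMap(pd.DataFrame(rows))


def make_comparison_frame(rows: list[dict]) -> ComparisonSet:
    """Build a ComparisonSet from shorthand row dicts."""
    defaults = {
        "as_type": "CASSETTE", "delta_psi": 0.0, "delta_psi_first": 0.0,
        "p_value": 1.0, "q_value": 1.0, "significant": False,
        "n_a": 3, "n_b": 3,
    }
    full = [{**defaults, **r} for r in rows]
    return ComparisonSet(pd.DataFrame(full))


def random_comparison_set(rng: np.random.Generator, n_cells: int, n_events: int):
    """A random ComparisonSet plus matching annotations, for oracle checks."""
    cells = [f"C{i}" for i in range(n_cells)]
    annotations = {}
    rows = []
    for e in range(n_events):
        as_type = rng.choice(list(synthetic.AS_TYPES))
        strand = rng.choice(["+", "-"])
        eid = f"e{e}"
        annotations[eid] = EventAnnotation(
            event_id=eid, gene_id=f"g{e}", chrom="chrI", strand=strand,
            as_type=as_type, starts=(100, 300), ends=(200, 400),
            inclusion_index=0 if as_type in ("CASSETTE", "IR") else None,
        )
        for a in cells:
            for b in cells:
                if a == b or rng.random() < 0.2:  # some pairs undetected
                    continue
                delta_first = float(rng.uniform(-1, 1))
                rows.append({
                    "as_type": as_type, "event_id": eid, "cell_a": a, "cell_b": b,
                    "delta_psi": delta_first, "delta_psi_first": delta_first,
                    "p_value": 0.01, "q_value": 0.01,
                    "significant": bool(rng.random() < 0.5),
                    "n_a": 3, "n_b": 3,
                })
    frame = pd.DataFrame(rows) if rows else pd.DataFrame()
    return ComparisonSet(frame, cell_types=cells), annotations
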