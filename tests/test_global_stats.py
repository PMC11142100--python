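"""Global quantification: count matrices, totals, correlations, outliers,
directional bias, mega matrices."""

import numpy as np
import pandas as pd
import pytest

from spliceuniq import events, global_stats, pairwise, synthetic
from spliceuniq.types import UniquenessRecord

from conftest import make_comparison_frame


class TestCountDifferential:
    def test_recount_oracle(self, small_comparisons):
        counts = global_stats.count_differential(small_comparisons)
        frame = small_comparisons.frame
        for row in counts.sample(50, random_state=0).itertuples(index=False):
            manual = len(frame[
                (frame["as_type"] == row.as_type)
                & (frame["cell_a"] == row.cell_a)
                & (frame["cell_b"] == row.cell_b)
                & frame["significant"]
            ])
            assert manual == row.n_significant

    def test_zero_for_quiet_pairs(self):
        comparisons = make_comparison_frame([
            {"event_id": "e1", "cell_a": "A", "cell_b": "B", "significant": True},
            {"event_id": "e2", "cell_a": "A", "cell_b": "B", "significant": True},
            {"event_id": "e3", "cell_a": "A", "cell_b": "B", "significant": True},
            {"event_id": "e1", "cell_a": "B", "cell_b": "A", "significant": True},
            {"event_id": "e1", "cell_a": "A", "cell_b": "C", "significant": False},
        ])
        counts = global_stats.count_differential(comparisons)
        lookup = counts.set_index(["as_type", "cell_a", "cell_b"])["n_significant"]
        assert lookup[("CASSETTE", "A", "B")] == 3
        assert lookup[("CASSETTE", "A", "C")] == 0

    def test_order_invariant(self, small_comparisons):
        shuffled = small_comparisons.frame.sample(frac=1, random_state=1)
        c1 = global_stats.count_differential(small_comparisons)
        c2 = global_stats.count_differential(
            type(small_comparisons)(shuffled, cell_types=small_comparisons.cell_types))
        pd.testing.assert_frame_equal(
            c1.sort_values(["as_type", "cell_a", "cell_b"]).reset_index(drop=True),
            c2.sort_values(["as_type", "cell_a", "cell_b"]).reset_index(drop=True),
        )


class TestGlobalTotals:
    def make_comparisons(self, n_calls: int):
        rows = []
        for i in range(n_calls):
            rows.append({"event_id": "e1", "cell_a": "A", "cell_b": f"X{i}",
                         "significant": True})
        return make_comparison_frame(rows)

    @pytest.mark.parametrize("n_calls,expected", [(6, 1), (4, 0)])
    def test_five_comparison_threshold(self, n_calls, expected, cassette_event):
        comparisons = self.make_comparisons(n_calls)
        annotations = {"e1": type(cassette_event)(
            "e1", "g1", "chrI", "+", "CASSETTE", (100, 100), (200, 400), 0)}
        totals = global_stats.global_totals(comparisons, annotations)
        row = totals[totals["as_type"] == "CASSETTE"].iloc[0]
        assert row["n_differential_events"] == expected
        assert row["n_differential_genes"] == expected

    def test_planted_class_dominates(self):
        # a simulation planted only with IR events shows IR as the largest
        # differential fraction
        config = synthetic.SimConfig(
            n_cell_types=8, n_replicates=4,
            events_per_type={t: 10 for t in synthetic.AS_TYPES},
            planted_fraction=0.0, seed=3,
        )
        counts, annotations, sample_map, _ = synthetic.simulate_splicing(config)
        # plant strong IR-only effects by hand: focal cell gets inverted usage
        ir_events = [e for e, a in annotations.items() if a.as_type == "IR"][:5]
        focal = sample_map.samples_for("CT1")
        idx = pd.IndexSlice
        for e in ir_events:
            block = counts.loc[idx[e, :], focal].to_numpy()
            counts.loc[idx[e, :], focal] = block[::-1]
        psi = events.compute_psi(counts, annotations, sample_map)
        comparisons = pairwise.run_all_pairs(psi, annotations)
        totals = global_stats.global_totals(comparisons, annotations)
        best = totals.loc[totals["fraction_of_differential"].idxmax(), "as_type"]
        assert best == "IR"


class TestCorrelation:
    def make_counts(self, values_by_type: dict[str, list[float]]):
        pairs = [("A", "B"), ("A", "C"), ("B", "C"), ("A", "D"), ("B", "D")]
        rows = []
        for as_type, values in values_by_type.items():
            for (a, b), v in zip(pairs, values):
                rows.append({"as_type": as_type, "cell_a": a, "cell_b": b,
                             "n_significant": int(v)})
                rows.append({"as_type": as_type, "cell_a": b, "cell_b": a,
                             "n_significant": int(v)})
        return pd.DataFrame(rows)

    def test_identity_regression(self):
        counts = self.make_counts({"CASSETTE": [1, 2, 3, 4, 5],
                                   "IR": [1, 2, 3, 4, 5]})
        corr = global_stats.splice_type_correlation(counts)
        assert corr.loc["CASSETTE", "IR"] == pytest.approx(1.0)

    def test_hand_computed_adjusted_r2(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0]
        counts = self.make_counts({"CASSETTE": x, "IR": y})
        corr = global_stats.splice_type_correlation(counts)
        # closed form: r2 from Pearson, adj = 1 - (1-r2)(m-1)/(m-2)
        r = np.corrcoef(x, y)[0, 1]
        expected = 1 - (1 - r * r) * 4 / 3
        assert corr.loc["CASSETTE", "IR"] == pytest.approx(expected)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(9)
        cells = [f"C{i}" for i in range(33)]  # 528 unordered pairs
        rows = []
        for a_i, a in enumerate(cells):
            for b in cells[a_i + 1:]:
                for t in ("CASSETTE", "IR"):
                    v = int(rng.integers(0, 50))
                    rows.append({"as_type": t, "cell_a": a, "cell_b": b,
                                 "n_significant": v})
        corr = global_stats.splice_type_correlation(pd.DataFrame(rows))
        assert abs(corr.loc["CASSETTE", "IR"]) < 0.1

    def test_constant_vector_zero_with_warning(self):
        counts = self.make_counts({"CASSETTE": [1, 2, 3, 4, 5],
                                   "IR": [2, 2, 2, 2, 2]})
        with pytest.warns(UserWarning, match="degenerate"):
            corr = global_stats.splice_type_correlation(counts)
        assert corr.loc["CASSETTE", "IR"] == 0.0


class TestOutliers:
    def make_counts(self, totals: dict[str, int]):
        cells = list(totals)
        rows = []
        for a in cells:
            others = [c for c in cells if c != a]
            per = totals[a] // len(others)
            for b in others:
                rows.append({"as_type": "A3S", "cell_a": a, "cell_b": b,
                             "n_significant": per})
        return pd.DataFrame(rows)

    def test_extreme_cell_flagged(self):
        counts = self.make_counts({"OLL": 500, **{f"C{i}": 50 for i in range(8)}})
        out = global_stats.outlier_cells(counts, "A3S")
        flagged = out[out["outlier"]]["cell_type"].tolist()
        assert flagged == ["OLL"]

    def test_homogeneous_none_flagged(self):
        rows = [{"as_type": "A3S", "cell_a": f"C{i}", "cell_b": "x",
                 "n_significant": 40 + 2 * i} for i in range(9)]
        out = global_stats.outlier_cells(pd.DataFrame(rows), "A3S")
        assert not out["outlier"].any()

    def test_planted_excess_flagged_per_type(self):
        # one cell with excess A3S only: flagged for A3S, not CASSETTE
        rows = []
        for t, excess in (("A3S", 400), ("CASSETTE", 40)):
            for a in ["OLL"] + [f"C{i}" for i in range(8)]:
                total = excess if (a == "OLL" and t == "A3S") else 40
                rows.append({"as_type": t, "cell_a": a, "cell_b": "x",
                             "n_significant": total})
        counts = pd.DataFrame(rows)
        a3s = global_stats.outlier_cells(counts, "A3S")
        cassette = global_stats.outlier_cells(counts, "CASSETTE")
        assert a3s[a3s["cell_type"] == "OLL"]["outlier"].item()
        assert not cassette["outlier"].any()


class TestDirectionalBias:
    def make_records(self, indices):
        return [UniquenessRecord(f"e{i}", "OLL", v, 1 if v else 0, 5, "A3S")
                for i, v in enumerate(indices)]

    def test_five_of_six_upstream(self):
        bias = global_stats.directional_bias(
            self.make_records([0.3, 0.2, -0.4, 0.5, 0.1, 0.6]), "OLL")
        assert bias == pytest.approx(5 / 6)

    def test_all_positive(self):
        assert global_stats.directional_bias(
            self.make_records([0.3, 0.2]), "OLL") == 1.0

    def test_empty_is_undefined(self):
        assert global_stats.directional_bias(
            self.make_records([0.0, 0.0]), "OLL") is None


class TestMegaMatrix:
    def test_replicate_mean(self):
        counts, annotations, sample_map = synthetic.constant_psi_dataset(
            3, 3, focal_psi=0.8, other_psi=0.2)
        psi = events.compute_psi(counts, annotations, sample_map)
        # perturb CT1's replicates to 0.7 / 0.8 / 0.9
        event = "CASSETTE_0000"
        for sample, value in zip(sample_map.samples_for("CT1"), (0.7, 0.8, 0.9)):
            psi.psi.loc[event, sample] = value
        usage = global_stats.usage_mega_matrix(psi, annotations)
        assert usage["CASSETTE"].loc[event, "CT1"] == pytest.approx(0.8)

    def test_undetected_missing_not_zero(self):
        counts, annotations, sample_map = synthetic.constant_psi_dataset(
            3, 3, focal_psi=0.8, other_psi=0.2)
        for s in sample_map.samples_for("CT2"):
            counts[s] = 0
        psi = events.compute_psi(counts, annotations, sample_map)
        usage = global_stats.usage_mega_matrix(psi, annotations)
        assert np.isnan(usage["CASSETTE"].loc["CASSETTE_0000", "CT2"])

    def test_row_union_and_range(self, small_sim, small_psi):
        _, annotations, _, _ = small_sim
        usage = global_stats.usage_mega_matrix(small_psi, annotations)
        total_rows = sum(len(m) for m in usage.values())
        union = {e for m in usage.values() for e in m.index}
        assert total_rows == len(union)
        for matrix in usage.values():
            vals = matrix.to_numpy()
            vals = vals[~np.isnan(vals)]
            assert ((vals >= 0) & (vals <= 1)).all()
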