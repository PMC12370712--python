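import numpy as np
import pandas as pd
import pytest

from hyperhealth import (
    ModalityFeatureTable,
    MultimodalDataset,
    PreprocessSpec,
    fuse_modalities,
    knn_hyperedges,
    preprocess_table,
    summarize_timeseries,
)
from hyperhealth.hypergraph import degrees


def table(ids, X, name="physiological"):
    return ModalityFeatureTable(name, tuple(ids), np.asarray(X, dtype=float))


class TestPreprocessTable:
    def test_mean_imputation_uses_fit_rows_only(self):
        raw = pd.DataFrame({"node_id": list("abc"), "x": [1.0, np.nan, 3.0]})
        t = preprocess_table(raw, PreprocessSpec(normalize="none"), ["a", "b", "c"])
        assert t.features[:, 0].tolist() == [1.0, 2.0, 3.0]
        # fit on {a} only: the missing value becomes a's value, not the global mean
        t2 = preprocess_table(raw, PreprocessSpec(normalize="none"), ["a"])
        assert t2.features[1, 0] == 1.0

    def test_population_zscore(self):
        raw = pd.DataFrame({"node_id": ["a", "b"], "x": [0.0, 2.0]})
        t = preprocess_table(raw, PreprocessSpec(), ["a", "b"])
        assert np.allclose(t.features[:, 0], [-1.0, 1.0])

    def test_mode_imputation_and_unknown_category(self):
        raw = pd.DataFrame({"node_id": list("abc"), "c": ["A", "A", None]})
        t = preprocess_table(raw, PreprocessSpec(normalize="none"), list("abc"))
        assert t.feature_names == ("c=A",)
        assert t.features[:, 0].tolist() == [1.0, 1.0, 1.0]
        t2 = preprocess_table(
            raw, PreprocessSpec(categorical_impute="unknown", normalize="none"), list("abc"))
        assert "c=Unknown" in t2.feature_names

    def test_constant_column_unit_divisor(self):
        raw = pd.DataFrame({"node_id": ["a", "b"], "x": [5.0, 5.0]})
        t = preprocess_table(raw, PreprocessSpec(), ["a", "b"])
        assert np.allclose(t.features[:, 0], 0.0)

    def test_entirely_missing_fit_column_rejected(self):
        raw = pd.DataFrame({"node_id": ["a", "b"], "x": [np.nan, 1.0]})
        with pytest.raises(ValueError, match="entirely missing"):
            preprocess_table(raw, PreprocessSpec(), ["a"])

    def test_fit_statistics_invariant_to_test_row_order(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame({
            "node_id": [f"n{i}" for i in range(10)],
            "x": rng.standard_normal(10),
            "y": rng.standard_normal(10),
        })
        fit = [f"n{i}" for i in range(6)]
        t1 = preprocess_table(raw, PreprocessSpec(), fit)
        shuffled = pd.concat([raw.iloc[:6], raw.iloc[6:].sample(frac=1, random_state=1)])
        t2 = preprocess_table(shuffled, PreprocessSpec(), fit)
        lookup = dict(zip(t2.node_ids, t2.features))
        assert np.allclose(t1.features, np.array([lookup[i] for i in t1.node_ids]))


class TestSummarizeTimeseries:
    SPEC = PreprocessSpec(gap_interpolation_max=5.0, window_length=30.0)

    def test_constant_signal(self):
        t = np.arange(0, 120.0)
        out = summarize_timeseries(t, np.full(t.shape, 5.0), self.SPEC)
        assert np.allclose(out, [5.0, 0.0])

    def test_short_gap_linearly_interpolated(self):
        t = np.array([0.0, 1.0, 3.0])
        out = summarize_timeseries(t, np.zeros(3), PreprocessSpec(window_length=3.0))
        assert np.allclose(out, [0.0, 0.0])

    def test_windows_over_long_gap_dropped(self):
        """Brute force: with a 10 s gap (threshold 5 s), only windows fully
        clear of the gap contribute."""
        t1 = np.arange(0.0, 30.0)       # window [0, 30) clean, value 1
        t2 = np.arange(40.0, 100.0)     # gap (29, 40) hits windows [0,30)? no: 29<30
        times = np.concatenate([t1, t2])
        values = np.concatenate([np.ones_like(t1), np.full_like(t2, 3.0)])
        out = summarize_timeseries(times, values, self.SPEC)
        # gap (29, 40) intersects [0,30) and [30,60); only [60,90) survives
        assert out[0] == pytest.approx(3.0)

    def test_all_windows_dropped_raises(self):
        t = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="no retained windows"):
            summarize_timeseries(t, np.zeros(3), self.SPEC)


class TestKnnHyperedges:
    def test_1d_nearest_neighbors(self):
        t = table(["a", "b", "c"], [[0.0], [1.0], [10.0]])
        h = knn_hyperedges(t, Z=1)
        # hyperedges (one per centroid): {a,b}, {b,a}, {c,b}
        expected = np.array([[1, 1, 0], [1, 1, 1], [0, 0, 1]], dtype=float)
        assert np.array_equal(h.incidence, expected)

    def test_saturated_Z_gives_complete_hyperedges(self):
        rng = np.random.default_rng(0)
        t = table([f"n{i}" for i in range(6)], rng.standard_normal((6, 3)))
        h = knn_hyperedges(t, Z=5)
        assert np.all(h.incidence == 1.0)

    def test_matches_bruteforce_distance_oracle(self):
        """Each hyperedge holds the centroid plus its Z nearest others, ties
        broken by ascending index."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n, Z = int(rng.integers(5, 15)), int(rng.integers(1, 4))
            X = rng.standard_normal((n, 2))
            t = table([f"n{i}" for i in range(n)], X)
            h = knn_hyperedges(t, Z)
            for x in range(n):
                dist = np.linalg.norm(X - X[x], axis=1)
                order = sorted((dist[v], v) for v in range(n) if v != x)
                expected = {x} | {v for _, v in order[:Z]}
                assert set(np.flatnonzero(h.incidence[:, x])) == expected
                assert h.incidence[:, x].sum() == Z + 1

    def test_invariant_to_column_permutation_and_shift(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((12, 4))
        ids = [f"n{i}" for i in range(12)]
        h1 = knn_hyperedges(table(ids, X), 3)
        h2 = knn_hyperedges(table(ids, X[:, ::-1] + 7.5), 3)
        assert np.array_equal(h1.incidence, h2.incidence)

    def test_invalid_Z_rejected(self):
        t = table(["a", "b"], [[0.0], [1.0]])
        with pytest.raises(ValueError):
            knn_hyperedges(t, Z=2)


class TestFuseModalities:
    def _dataset(self, tables):
        n = tables[0].n_nodes
        return MultimodalDataset(tuple(tables), np.zeros(n, dtype=int) if n < 2
                                 else np.arange(n) % 2, ("train",) * n)

    def test_single_modality_is_identity(self):
        rng = np.random.default_rng(0)
        t = table([f"n{i}" for i in range(8)], rng.standard_normal((8, 3)))
        ds = self._dataset([t])
        X, h = fuse_modalities(ds, 2)
        assert np.array_equal(X, t.features)
        assert np.array_equal(h.incidence, knn_hyperedges(t, 2).incidence)

    def test_dimension_bookkeeping(self):
        rng = np.random.default_rng(0)
        ids = [f"n{i}" for i in range(9)]
        t1 = table(ids, rng.standard_normal((9, 2)), "physiological")
        t2 = table(ids, rng.standard_normal((9, 3)), "behavioral")
        X, h = fuse_modalities(self._dataset([t1, t2]), [2, 3])
        assert X.shape == (9, 5)
        assert h.n_edges == 2 * 9

    def test_identical_modalities_double_degrees(self):
        rng = np.random.default_rng(2)
        ids = [f"n{i}" for i in range(7)]
        F = rng.standard_normal((7, 3))
        t1, t2 = table(ids, F, "physiological"), table(ids, F, "behavioral")
        X, h = fuse_modalities(self._dataset([t1, t2]), 2)
        B1 = h.incidence[:, :7]
        B2 = h.incidence[:, 7:]
        assert np.array_equal(B1, B2)
        single = degrees(knn_hyperedges(t1, 2)).node_degrees
        assert np.array_equal(degrees(h).node_degrees, 2 * single)

    def test_fused_degrees_are_sums_of_modality_degrees(self):
        rng = np.random.default_rng(3)
        ids = [f"n{i}" for i in range(10)]
        tables = [table(ids, rng.standard_normal((10, d)), name)
                  for d, name in ((4, "physiological"), (3, "behavioral"), (2, "environmental"))]
        ds = self._dataset(tables)
        _, h = fuse_modalities(ds, [2, 3, 1])
        expected = sum(degrees(knn_hyperedges(t, z)).node_degrees
                       for t, z in zip(tables, [2, 3, 1]))
        assert np.array_equal(degrees(h).node_degrees, expected)

    def test_misaligned_ids_rejected(self):
        t1 = table(["a", "b", "c"], np.eye(3), "physiological")
        t2 = table(["a", "c", "b"], np.eye(3), "behavioral")
        with pytest.raises(ValueError, match="misaligned"):
            MultimodalDataset((t1, t2), np.zeros(3, dtype=int), ("train",) * 3)
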