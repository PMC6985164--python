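"""Drug-response tables, neighbour search, prediction and quadratic kappa."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score
from sklearn.neighbors import NearestNeighbors

from omicsfuse import (
    DrugResponseTable,
    NeighborSearcher,
    categorize_z,
    find_neighbors,
    leave_one_out_benchmark,
    predict_drug_response,
    quadratic_kappa,
)


def _table_from_z(line_ids, drug_ids, z):
    z = np.asarray(z, dtype=float)
    return DrugResponseTable(
        line_ids=list(line_ids),
        drug_ids=list(drug_ids),
        activity=z.copy(),
        z=z,
        categories=categorize_z(z),
    )


class TestTable:
    def test_z_normalization_idempotent(self, rng):
        act = rng.normal(2.0, 3.0, size=(20, 5))
        t1 = DrugResponseTable.from_activity(
            [f"L{i}" for i in range(20)], [f"d{j}" for j in range(5)], act
        )
        t2 = DrugResponseTable.from_activity(t1.line_ids, t1.drug_ids, t1.z)
        np.testing.assert_allclose(t2.z, t1.z, atol=1e-12)

    def test_boundary_z_values_are_intermediate(self):
        cats = categorize_z(np.array([0.8, -0.8, 0.8000001, -0.8000001, 0.0]))
        assert cats.tolist() == [1.0, 1.0, 2.0, 0.0, 1.0]

    def test_missing_entries_stay_missing(self):
        act = np.array([[1.0, np.nan], [2.0, 0.5], [3.0, 1.5]])
        t = DrugResponseTable.from_activity(["a", "b", "c"], ["d1", "d2"], act)
        assert np.isnan(t.z[0, 1]) and np.isnan(t.categories[0, 1])

    def test_zero_variance_drug_rejected(self):
        act = np.array([[1.0], [1.0], [1.0]])
        with pytest.raises(ValueError, match="zero variance"):
            DrugResponseTable.from_activity(["a", "b", "c"], ["d"], act)


class TestNeighborSearch:
    def test_line_toy_hand_distances(self):
        refs = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        sr = NeighborSearcher(
            ids=[f"L{i}" for i in range(5)], profiles=refs, feature_ids=["g"],
            standardize=False,
        )
        ids, d2 = find_neighbors(sr, query_profile=np.array([1.4]), n=2)
        assert ids == ["L1", "L2"]
        np.testing.assert_allclose(d2, [0.16, 0.36])

    def test_identical_reference_first_with_zero_distance(self, rng):
        refs = rng.normal(size=(10, 3))
        sr = NeighborSearcher(
            ids=[f"L{i}" for i in range(10)], profiles=refs,
            feature_ids=list("abc"), standardize=False,
        )
        ids, d2 = find_neighbors(sr, query_profile=refs[4], n=3)
        assert ids[0] == "L4" and d2[0] == 0.0

    def test_oversized_n_returns_all_with_warning(self, rng, caplog):
        refs = rng.normal(size=(4, 2))
        sr = NeighborSearcher(ids=list("wxyz"), profiles=refs, feature_ids=["a", "b"])
        with caplog.at_level("WARNING"):
            ids, _ = find_neighbors(sr, query_id="w", n=10)
        assert len(ids) == 3  # self excluded
        assert "returning all" in caplog.text

    def test_matches_brute_force_scan(self, rng):
        # oracle: sklearn exhaustive NearestNeighbors on the same matrix
        refs = rng.normal(size=(80, 6))
        sr = NeighborSearcher(
            ids=[f"L{i:02d}" for i in range(80)], profiles=refs,
            feature_ids=[f"g{j}" for j in range(6)], standardize=False,
        )
        nn = NearestNeighbors(n_neighbors=11, algorithm="brute").fit(refs)
        for q in [0, 7, 42]:
            ids, d2 = find_neighbors(sr, query_id=f"L{q:02d}", n=10)
            dist, idx = nn.kneighbors(refs[q : q + 1])
            expected = [f"L{i:02d}" for i in idx[0] if i != q][:10]
            assert ids == expected
            np.testing.assert_allclose(d2, np.sort(dist[0][1:]) ** 2, atol=1e-10)


class TestPrediction:
    def _searcher(self, profiles, ids):
        return NeighborSearcher(
            ids=ids, profiles=profiles,
            feature_ids=[f"g{j}" for j in range(profiles.shape[1])],
            standardize=False,
        )

    def test_median_of_neighbor_z_then_categorize(self):
        # query q sits next to n1 and n2 only
        profiles = np.array([[0.0], [0.1], [-0.1], [50.0]])
        sr = self._searcher(profiles, ["q", "n1", "n2", "far"])
        table = _table_from_z(
            ["n1", "n2", "far"], ["dA", "dB"],
            [[1.0, 1.0], [1.2, -1.0], [0.0, 0.0]],
        )
        pred = predict_drug_response("q", sr, table, n=2)
        # dA: median(1.0, 1.2) = 1.1 -> sensitive; dB: median(1.0, -1.0) = 0 -> intermediate
        assert pred.tolist() == [2.0, 1.0]

    def test_two_data_bearing_neighbors_median_equals_mean(self):
        profiles = np.array([[0.0], [0.1], [-0.1], [0.2], [0.3]])
        sr = self._searcher(profiles, ["q", "n1", "n2", "n3", "n4"])
        # only n1 and n4 carry drug data; n2, n3 are skipped, not widened
        table = _table_from_z(["n1", "n4"], ["dA"], [[0.5], [0.9]])
        pred = predict_drug_response("q", sr, table, n=4)
        assert pred[0] == categorize_z((0.5 + 0.9) / 2)

    def test_no_data_bearing_neighbor_errors(self):
        profiles = np.array([[0.0], [0.1]])
        sr = self._searcher(profiles, ["q", "n1"])
        table = _table_from_z(["other"], ["dA"], [[1.0]])
        with pytest.raises(ValueError, match="drug-response data"):
            predict_drug_response("q", sr, table, n=1)


class TestQuadraticKappa:
    def test_perfect_agreement(self):
        assert quadratic_kappa([0, 1, 2, 1], [0, 1, 2, 1]) == 1.0

    def test_hand_contingency_oracle(self):
        pred, actual = [0, 1, 2, 1], [0, 2, 2, 1]
        # brute-force evaluation of the definition
        C = 3
        O = np.zeros((C, C))
        for p_, a_ in zip(pred, actual):
            O[p_, a_] += 1
        E = np.outer(O.sum(1), O.sum(0)) / O.sum()
        w = np.array([[(i - j) ** 2 for j in range(C)] for i in range(C)]) / (C - 1) ** 2
        expected = 1 - (w * O).sum() / (w * E).sum()
        assert quadratic_kappa(pred, actual) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_on_random_pairs(self, rng):
        # independent oracle: sklearn's quadratic-weighted kappa
        for _ in range(50):
            n = int(rng.integers(5, 60))
            a = rng.integers(0, 3, size=n)
            b = rng.integers(0, 3, size=n)
            if len(set(a)) == 1 and len(set(b)) == 1:
                continue
            ours = quadratic_kappa(a, b)
            ref = cohen_kappa_score(a, b, weights="quadratic", labels=[0, 1, 2])
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_long_independent_pairs_near_zero(self, rng):
        a = rng.integers(0, 3, size=100_000)
        b = rng.integers(0, 3, size=100_000)
        assert abs(quadratic_kappa(a, b)) < 0.05

    def test_scale_reversal_invariance(self, rng):
        a = rng.integers(0, 3, size=200)
        b = rng.integers(0, 3, size=200)
        assert quadratic_kappa(2 - a, 2 - b) == pytest.approx(
            quadratic_kappa(a, b), abs=1e-12
        )

    def test_constant_rater_conventions(self):
        assert quadratic_kappa([1, 1, 1], [1, 1, 1]) == 1.0
        # constant raters disagreeing everywhere: denominator positive
        assert quadratic_kappa([0, 0, 0], [2, 2, 2]) == 0.0

    def test_missing_pairs_dropped_and_empty_rejected(self):
        assert quadratic_kappa([0, np.nan, 2], [0, 1, 2]) == 1.0
        with pytest.raises(ValueError, match="usable"):
            quadratic_kappa([np.nan], [1])


class TestBenchmark:
    def test_single_drug_switches_to_pooled_kappa(self, rng, caplog):
        profiles = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(5, 0.1, (5, 2))])
        ids = [f"L{i}" for i in range(10)]
        z = np.concatenate([np.full(5, 1.2), np.full(5, -1.2)])
        # tiny jitter so the per-drug z-scores are not literally constant
        table = _table_from_z(ids, ["dA"], z[:, None])
        sr = NeighborSearcher(ids=ids, profiles=profiles, feature_ids=["a", "b"],
                              standardize=False)
        with caplog.at_level("INFO"):
            res = leave_one_out_benchmark(table, sr, n=3)
        assert res.pooled
        assert res.mean_kappa == pytest.approx(1.0)
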