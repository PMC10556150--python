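"""Manhattan k-means, exemplar selection, k choice, emergence ordering."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from dfnckit import (
    ManhattanKMeans,
    WindowedFNCSeries,
    assign_states,
    choose_k,
    fit_states,
    select_exemplars,
    state_summary,
)
from dfnckit.types import NetworkPartition

PART6 = NetworkPartition(sizes=(2, 2, 2))


def series_from(data: np.ndarray, sid: str = "s") -> WindowedFNCSeries:
    return WindowedFNCSeries(
        subject_id=sid, data=data,
        window_starts=np.arange(data.shape[0]), lambda_used=0.1,
        partition=PART6,
    )


def brute_force_best_2partition(X: np.ndarray) -> float:
    """Exhaustive best 2-cluster L1 cost with median centers."""
    n = X.shape[0]
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        lab = np.array((0,) + bits)
        if lab.max() == 0:
            continue
        cost = sum(
            np.abs(X[lab == j] - np.median(X[lab == j], axis=0)).sum()
            for j in (0, 1)
        )
        best = min(best, cost)
    return best


class TestManhattanKMeans:
    def test_k_distinct_points_zero_cost(self, rng):
        X = rng.standard_normal((5, 3)) * 10
        km = ManhattanKMeans(n_clusters=5, random_state=0).fit(X)
        assert km.inertia_ == pytest.approx(0.0, abs=1e-12)
        assert sorted(map(tuple, km.cluster_centers_)) == sorted(map(tuple, X))

    def test_matches_exhaustive_best_2partition(self, rng):
        X = np.vstack([
            rng.standard_normal((6, 2)) + [0, 0],
            rng.standard_normal((6, 2)) + [6, 6],
        ])
        km = ManhattanKMeans(n_clusters=2, n_init=5, random_state=0).fit(X)
        assert km.inertia_ == pytest.approx(brute_force_best_2partition(X), abs=1e-9)
        # blob membership recovered exactly
        assert len(set(km.labels_[:6])) == 1 and len(set(km.labels_[6:])) == 1

    def test_centroids_invariant_under_row_duplication(self, rng):
        # well-separated blobs make the optimum unique, so duplication
        # must leave the (median) centroids untouched
        X = np.vstack([
            rng.standard_normal((10, 4)) + off
            for off in ([0, 0, 0, 0], [8, 8, 8, 8], [-8, 8, -8, 8])
        ])
        km1 = ManhattanKMeans(n_clusters=3, n_init=5, random_state=1).fit(X)
        km2 = ManhattanKMeans(n_clusters=3, n_init=5, random_state=1).fit(
            np.vstack([X, X])
        )
        c1 = np.array(sorted(map(tuple, km1.cluster_centers_)))
        c2 = np.array(sorted(map(tuple, km2.cluster_centers_)))
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_cost_non_increasing_and_best_of_n_init(self, rng):
        X = rng.standard_normal((60, 5))
        km = ManhattanKMeans(n_clusters=4, n_init=5, random_state=2).fit(X)
        assert all(
            b <= a + 1e-9 for a, b in zip(km.cost_history_, km.cost_history_[1:])
        )
        assert km.inertia_ <= min(km.run_costs_) + 1e-9

    def test_predict_tie_breaks_to_lowest_index(self):
        km = ManhattanKMeans(n_clusters=2, random_state=0)
        km.cluster_centers_ = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert km.predict(np.array([[1.0, 0.0]]))[0] == 0

    def test_predict_matches_brute_force_nearest(self, rng):
        centers = rng.standard_normal((4, 6))
        km = ManhattanKMeans(n_clusters=4)
        km.cluster_centers_ = centers
        X = rng.standard_normal((50, 6))
        expected = np.array([
            int(np.argmin([np.abs(x - c).sum() for c in centers])) for x in X
        ])
        np.testing.assert_array_equal(km.predict(X), expected)

    def test_more_clusters_than_points_rejected(self, rng):
        with pytest.raises(ValueError, match="clusters"):
            ManhattanKMeans(n_clusters=5).fit(rng.standard_normal((3, 2)))


class TestExemplars:
    @staticmethod
    def series_with_variance(v: np.ndarray) -> WindowedFNCSeries:
        # two pairs valued +/- sqrt(v) give across-pair variance v
        data = np.column_stack([np.sqrt(v), -np.sqrt(v), np.zeros_like(v)])
        data = np.hstack([data, np.zeros((v.size, 12))])
        return series_from(data)

    def test_monotone_variance_selects_last_window(self):
        s = self.series_with_variance(np.linspace(0.1, 2.0, 20))
        X, owners = select_exemplars([s])
        assert X.shape[0] == 1
        np.testing.assert_array_equal(X[0], s.data[-1])

    def test_two_peaks_selected(self):
        v = np.full(60, 0.1)
        v[10], v[50] = 2.0, 3.0
        s = self.series_with_variance(v)
        X, _ = select_exemplars([s])
        assert X.shape[0] == 2
        np.testing.assert_array_equal(X[0], s.data[10])
        np.testing.assert_array_equal(X[1], s.data[50])

    def test_flat_variance_falls_back_to_first_max(self):
        s = self.series_with_variance(np.full(10, 1.0))
        X, _ = select_exemplars([s])
        assert X.shape[0] == 1
        np.testing.assert_array_equal(X[0], s.data[0])


class TestChooseK:
    @staticmethod
    def planted_blobs(rng, k: int, n_per: int = 40, sep: float = 8.0):
        centers = rng.standard_normal((k, 10)) * sep
        return np.vstack([
            centers[j] + rng.standard_normal((n_per, 10)) for j in range(k)
        ])

    def test_recovers_two_planted_clusters(self, rng):
        # silhouette recovers an endpoint of the candidate range; a kink
        # criterion on the cost curve cannot, by construction
        X = self.planted_blobs(rng, 2)
        k, _ = choose_k(X, range(2, 7), "silhouette", seed=0)
        assert k == 2

    def test_recovers_four_planted_clusters(self, rng):
        X = self.planted_blobs(rng, 4)
        for method in ("elbow", "silhouette"):
            k, diag = choose_k(X, range(2, 9), method, seed=0)
            assert k == 4, diag

    def test_null_blob_does_not_crash_and_reports_curves(self, rng):
        X = rng.standard_normal((80, 5))
        k, diag = choose_k(X, range(2, 7), "silhouette", seed=0)
        assert set(diag["silhouette"]) == {2, 3, 4, 5, 6}
        assert max(diag["silhouette"].values()) < 0.3  # no strong optimum

    def test_elbow_needs_three_candidates(self, rng):
        with pytest.raises(ValueError, match="3 candidate"):
            choose_k(rng.standard_normal((20, 3)), [2, 3], "elbow", seed=0)


class TestStateModelAndAssignment:
    @staticmethod
    def toy_series(rng, n_subjects=4, n_windows=30):
        centers = np.array([[5.0] * 15, [-5.0] * 15, [5.0] * 7 + [-5.0] * 8])
        out = []
        for i in range(n_subjects):
            lab = rng.integers(3, size=n_windows)
            data = centers[lab] + 0.3 * rng.standard_normal((n_windows, 15))
            out.append(series_from(data, f"s{i}"))
        return out

    def test_assign_exact_match_and_tie_break(self):
        centroids = np.array([[0.0] * 15, [1.0] * 15])
        s = series_from(np.vstack([centroids[1], 0.5 * np.ones(15)]))
        labels = assign_states([s], centroids)["s"]
        assert labels[0] == 2  # exact match with centroid 2
        assert labels[1] == 1  # equidistant -> lowest index

    def test_assign_matches_exhaustive_scan(self, rng):
        centroids = rng.standard_normal((4, 15))
        s = series_from(rng.standard_normal((25, 15)))
        labels = assign_states([s], centroids)["s"]
        expected = 1 + np.array([
            int(np.argmin([np.abs(x - c).sum() for c in centroids]))
            for x in s.data
        ])
        np.testing.assert_array_equal(labels, expected)

    def test_dimension_mismatch_rejected(self, rng):
        s = series_from(rng.standard_normal((5, 15)))
        with pytest.raises(ValueError, match="dimension"):
            assign_states([s], rng.standard_normal((4, 9)))

    def test_emergence_order_is_first_occurrence(self, rng):
        series = self.toy_series(rng)
        model = fit_states(series, k=3, seed=0)
        flat = model.concatenated_labels()
        firsts = [int(np.flatnonzero(flat == s)[0]) for s in (1, 2, 3)]
        assert firsts == sorted(firsts)
        assert flat[0] == 1

    def test_relabeling_is_pure_permutation(self, rng):
        series = self.toy_series(rng)
        m1 = fit_states(series, k=3, seed=0, two_stage=False)
        km = ManhattanKMeans(n_clusters=3, n_init=5, random_state=0).fit(
            np.vstack([s.data for s in series])
        )
        # same partition of windows, possibly different label names
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(m1.concatenated_labels(), km.labels_) == 1.0
        assert m1.inertia == pytest.approx(km.inertia_, rel=1e-9)

    def test_state_summary_counts_and_percentages(self, rng):
        series = self.toy_series(rng)
        model = fit_states(series, k=3, seed=0)
        summary = state_summary(model)
        assert summary["n_windows"].sum() == sum(s.n_windows for s in series)
        assert summary["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_state_occupancy_is_degenerate(self):
        data = np.tile(np.linspace(1, 2, 15), (10, 1))
        model = fit_states([series_from(data)], k=1, seed=0)
        summary = state_summary(model)
        assert summary["percent"].tolist() == [100.0]
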