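"""Tests of the longitudinal k-means machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import mhladr_endotypes as m
from mhladr_endotypes.kml import (
    IncomparableTrajectoriesError,
    TrajectoryCohort,
    _single_restart,
    calinski_harabasz,
    gower_distance,
    impute_copy_mean,
    mean_assignment_probability,
    posterior_probabilities,
)

from conftest import ANCHORS

nan = np.nan


def make_cohort(matrix, grid=(1.5, 3.5, 6.0)):
    matrix = np.asarray(matrix, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n = matrix.shape[0]
    return TrajectoryCohort(
        patients=np.array([f"P{i}" for i in range(n)]),
        grid=grid,
        matrix=matrix,
        days=np.where(np.isnan(matrix), np.nan, np.tile(grid, (n, 1))),
        cohort=np.array(["all"] * n, dtype=object),
    )


class TestGowerDistance:
    def test_identical_complete_trajectories(self):
        assert gower_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_partial_overlap_rescaled(self):
        # shared coordinates 0 and 2: sqrt((3/2) * (0 + 4)) = sqrt(6)
        d = gower_distance([1.0, 2.0, 3.0], [1.0, nan, 5.0])
        assert d == pytest.approx(np.sqrt(6.0))

    def test_no_shared_coordinate_rejected(self):
        with pytest.raises(IncomparableTrajectoriesError):
            gower_distance([1.0, nan, nan], [nan, 2.0, 3.0])

    @given(
        x=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        y=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
    )
    @settings(deadline=None, max_examples=100)
    def test_complete_pairs_equal_euclidean_and_symmetric(self, x, y):
        x, y = np.array(x), np.array(y)
        d = gower_distance(x, y)
        assert d == pytest.approx(np.linalg.norm(x - y), abs=1e-9)
        assert d == gower_distance(y, x)
        assert d >= 0.0


class TestCalinskiHarabasz:
    def test_matches_brute_force_on_hand_assignment(self):
        pts = np.array(
            [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [8, 8, 8], [9, 8, 8], [8, 9, 9]]
        )
        a = np.array([0, 0, 0, 1, 1, 1])
        grand = pts.mean(axis=0)
        tb = sum(
            (a == c).sum() * np.sum((pts[a == c].mean(axis=0) - grand) ** 2) for c in (0, 1)
        )
        tw = sum(np.sum((pts[a == c] - pts[a == c].mean(axis=0)) ** 2) for c in (0, 1))
        expected = (tb / 1) / (tw / 4)
        assert calinski_harabasz(pts, a) == pytest.approx(expected)

    def test_matches_sklearn_score(self):
        from sklearn.metrics import calinski_harabasz_score

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(40, 3))
        a = rng.integers(0, 3, size=40)
        assert calinski_harabasz(pts, a) == pytest.approx(calinski_harabasz_score(pts, a))

    def test_perfect_separation_returns_infinity(self):
        pts = np.array([[0.0, 0, 0], [0, 0, 0], [9, 9, 9], [9, 9, 9]])
        assert calinski_harabasz(pts, np.array([0, 0, 1, 1])) == np.inf

    def test_n_not_greater_than_k_rejected(self):
        with pytest.raises(ValueError, match="n > k"):
            calinski_harabasz(np.array([[0.0, 0, 0], [1, 1, 1]]), np.array([0, 1]))


class TestCopyMeanImputation:
    def test_interior_gap_carries_mean_shape_deviation(self):
        # equidistant grid; rows chosen so the cluster mean including the
        # imputed patient is exactly (10, 25, 30); patient (12, ., 32):
        # patient interp 22, mean interp 20, deviation +5 -> 27
        cohort = make_cohort(
            [[9.0, 25.0, 29.0], [9, 25, 29], [12, nan, 32]], grid=(1.0, 2.0, 3.0)
        )
        imputed = impute_copy_mean(cohort, np.zeros(3, dtype=int))
        np.testing.assert_allclose(np.nanmean(cohort.matrix, axis=0), [10, 25, 30])
        assert imputed[2, 1] == pytest.approx(27.0)

    def test_linear_cluster_mean_reduces_to_linear_interpolation(self):
        # rows chosen so the cluster mean stays linear on the (non-equidistant)
        # grid including the imputed patient -> deviation term vanishes
        grid = np.array([1.5, 3.5, 6.0])
        mu = 2.0 + 3.0 * grid  # target linear mean (6.5, 12.5, 20.0)
        rows = [
            [3 * mu[0] - 10.0 - mu[0], 2 * mu[1] - mu[1], 3 * mu[2] - 28.0 - mu[2]],
            [mu[0], mu[1], mu[2]],
            [10.0, nan, 28.0],
        ]
        cohort = make_cohort(rows)
        imputed = impute_copy_mean(cohort, np.zeros(3, dtype=int))
        w = (3.5 - 1.5) / (6.0 - 1.5)
        assert imputed[2, 1] == pytest.approx(10 + w * (28 - 10), rel=1e-6)

    def test_leading_gaps_copy_mean_level_difference(self):
        # patient (., ., 32), cluster mean including it (10, 25, 30) -> 12, 27
        cohort = make_cohort([[10.0, 25.0, 29.0], [10, 25, 29], [nan, nan, 32]])
        imputed = impute_copy_mean(cohort, np.zeros(3, dtype=int))
        np.testing.assert_allclose(imputed[2], [12.0, 27.0, 32.0])

    def test_observed_entries_untouched(self):
        rng = np.random.default_rng(8)
        matrix = rng.normal(size=(20, 3))
        matrix[rng.random(size=(20, 3)) < 0.2] = nan
        matrix[:, 0] = rng.normal(size=20)  # ensure everyone observed somewhere
        cohort = make_cohort(matrix)
        imputed = impute_copy_mean(cohort, rng.integers(0, 2, size=20))
        obs = ~np.isnan(matrix)
        np.testing.assert_array_equal(imputed[obs], matrix[obs])


class TestKMeans:
    def test_matches_standard_kmeans_on_complete_blobs(self, blob_cohort):
        cohort, truth = blob_cohort
        part = m.kmeans_longitudinal(cohort, k=2, n_restarts=20, seed=0)
        oracle = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(cohort.matrix)
        assert adjusted_rand_score(part.assignment, oracle) == 1.0
        assert adjusted_rand_score(part.assignment, truth) == 1.0

    def test_objective_non_increasing_within_restart(self):
        rng = np.random.default_rng(9)
        matrix = rng.normal(size=(60, 3))
        matrix[rng.random(size=(60, 3)) < 0.25] = nan
        matrix[np.isnan(matrix).all(axis=1), 0] = 0.0
        grand = np.nanmean(matrix, axis=0)
        for s in range(10):
            res = _single_restart(matrix, grand, np.random.default_rng(s), k=3)
            if res is None:
                continue
            _, _, trace = res
            diffs = np.diff(trace)
            assert (diffs <= 1e-9 * max(abs(trace[0]), 1.0)).all()

    def test_latent_endotypes_recovered_on_default_cohort(self, aggregated_run):
        part = aggregated_run["partition"]
        true = aggregated_run["labels"].reindex(aggregated_run["cohort"].patients).to_numpy()
        pred = np.array([part.names[c] for c in part.assignment])
        assert adjusted_rand_score(true, pred) >= 0.8

    def test_recovered_centers_match_generator_anchors(self, aggregated_run):
        centers = aggregated_run["centers_abc"]
        names = aggregated_run["partition"].names
        for c in range(4):
            d1, d6 = ANCHORS[names[c]]
            assert abs(centers[c, 0] - d1) / d1 < 0.10
            assert abs(centers[c, 2] - d6) / d6 < 0.10

    def test_partition_stable_under_patient_permutation(self, blob_cohort):
        cohort, _ = blob_cohort
        part = m.kmeans_longitudinal(cohort, k=2, n_restarts=20, seed=1)
        rng = np.random.default_rng(10)
        perm = rng.permutation(cohort.n_patients)
        shuffled = TrajectoryCohort(
            patients=cohort.patients[perm],
            grid=cohort.grid,
            matrix=cohort.matrix[perm],
            days=cohort.days[perm],
            cohort=cohort.cohort[perm],
        )
        part2 = m.kmeans_longitudinal(shuffled, k=2, n_restarts=20, seed=1)
        from mhladr_endotypes.compare import partition_concordance

        conc = partition_concordance(
            cohort.patients, part.assignment, shuffled.patients, part2.assignment
        )
        assert conc.agreement == 1.0

    def test_k_larger_than_n_rejected(self, blob_cohort):
        cohort, _ = blob_cohort
        with pytest.raises(ValueError, match="exceeds"):
            m.kmeans_longitudinal(cohort, k=cohort.n_patients + 1)

    def test_invariants_of_partition(self, aggregated_run):
        part = aggregated_run["partition"]
        n = part.posterior.shape[0]
        np.testing.assert_allclose(part.posterior.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(part.posterior.argmax(axis=1), part.assignment)
        obs = ~np.isnan(aggregated_run["cohort"].matrix)
        np.testing.assert_array_equal(
            part.imputed[obs], aggregated_run["cohort"].matrix[obs]
        )
        assert part.ch >= 0


class TestPosterior:
    def test_equidistant_patient_splits_evenly(self):
        imputed = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 0, 0]])
        centers = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        post = posterior_probabilities(imputed, centers, np.array([0, 1, 0]))
        np.testing.assert_allclose(post[2], [0.5, 0.5])

    def test_point_at_center_with_far_alternatives(self):
        imputed = np.array([[0.0, 0, 0], [0.01, 0, 0], [100.0, 0, 0], [100.01, 0, 0]])
        centers = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        post = posterior_probabilities(imputed, centers, np.array([0, 0, 1, 1]))
        assert post[0, 0] > 0.999

    def test_zero_dispersion_gives_one_hot(self):
        imputed = np.array([[0.0, 0, 0], [1.0, 1, 1]])
        centers = imputed.copy()
        post = posterior_probabilities(imputed, centers, np.array([0, 1]))
        np.testing.assert_array_equal(post, np.eye(2))

    def test_mean_assignment_probability_high_on_separated_cohort(self, aggregated_run):
        assert mean_assignment_probability(aggregated_run["partition"]) >= 0.78


class TestNaming:
    def test_published_centers_get_published_names(self):
        centers = np.array(
            [
                [3265.0, 3552, 3865],
                [31774, 18513, 10785],
                [6331, 7872, 9787],
                [9681, 16645, 28604],
            ]
        )
        names = m.name_endotypes(centers)
        assert names == {
            0: "Non-improvers",
            1: "Decliners",
            2: "Improvers",
            3: "High expressors",
        }

    def test_identical_centers_still_bijective(self):
        centers = np.full((4, 3), 5000.0)
        names = m.name_endotypes(centers)
        assert sorted(names.values()) == [
            "Decliners",
            "High expressors",
            "Improvers",
            "Non-improvers",
        ]

    def test_other_k_gets_generic_labels(self):
        names = m.name_endotypes(np.ones((3, 3)))
        assert names == {0: "C1", 1: "C2", 2: "C3"}


class TestFromLong:
    def test_pivot_assigns_windows_and_averages_duplicates(self):
        df = pd.DataFrame(
            {
                "patient_id": ["A", "A", "A", "A"],
                "day": [1.0, 2.0, 4.0, 6.0],
                "mhla_dr_t": [1.0, 3.0, 5.0, 7.0],
            }
        )
        cohort = TrajectoryCohort.from_long(df)
        np.testing.assert_allclose(cohort.matrix[0], [2.0, 5.0, 7.0])
        np.testing.assert_allclose(cohort.days[0], [1.5, 4.0, 6.0])

    def test_day_outside_windows_rejected(self):
        df = pd.DataFrame({"patient_id": ["A"], "day": [9.0], "mhla_dr_t": [1.0]})
        with pytest.raises(ValueError, match="window"):
            TrajectoryCohort.from_long(df)
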