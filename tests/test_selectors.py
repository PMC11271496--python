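"""Selector semantics and the local outlier factor machinery."""

import numpy as np
import pytest

from mlal.selectors import (
    DistanceSelectorConfig,
    EnergySelectorConfig,
    SelectorDecision,
    SimilaritySelectorConfig,
    dataset_lofs,
    distance_select,
    energy_select,
    lof_profile,
    lof_threshold,
    similarity_select,
)


# ---------------------------------------------------------------------------
# independent brute-force LOF oracle (pure python, textbook definitions)
# ---------------------------------------------------------------------------

def _brute_lof(o, X, k):
    X = [np.asarray(x, float) for x in X]
    o = np.asarray(o, float)

    def dist(a, b):
        return float(np.sqrt(((a - b) ** 2).sum()))

    def knn_of_point(p, exclude=None):
        ds = sorted(
            (dist(p, X[j]), j) for j in range(len(X)) if j != exclude
        )
        return [j for _, j in ds[:k]]

    def k_distance(i):
        ds = sorted(dist(X[i], X[j]) for j in range(len(X)) if j != i)
        return ds[k - 1]

    def lrd(i):
        neigh = knn_of_point(X[i], exclude=i)
        rd = [max(k_distance(j), dist(X[i], X[j])) for j in neigh]
        return 1.0 / (sum(rd) / len(rd))

    neigh_o = knn_of_point(o)
    rd_o = [max(k_distance(j), dist(o, X[j])) for j in neigh_o]
    lrd_o = 1.0 / (sum(rd_o) / len(rd_o))
    return sum(lrd(j) for j in neigh_o) / (len(neigh_o) * lrd_o)


def _brute_member_lofs(X, k):
    """Textbook LOF of every dataset member (self excluded from searches only)."""
    X = np.asarray(X, float)

    def dist(i, j):
        return float(np.sqrt(((X[i] - X[j]) ** 2).sum()))

    def knn(i):
        ds = sorted((dist(i, j), j) for j in range(len(X)) if j != i)
        return [j for _, j in ds[:k]]

    def k_distance(i):
        ds = sorted(dist(i, j) for j in range(len(X)) if j != i)
        return ds[k - 1]

    def lrd(i):
        rd = [max(k_distance(j), dist(i, j)) for j in knn(i)]
        return 1.0 / (sum(rd) / len(rd))

    return [sum(lrd(j) for j in knn(i)) / (k * lrd(i)) for i in range(len(X))]


class TestEnergySelector:
    @pytest.mark.parametrize(
        "delta, verdict",
        [
            (0.5, "skip"),      # below threshold
            (1.0, "skip"),      # boundary: not strictly above E_T
            (5.0, "add"),       # between E_T and 10·E_T
            (10.0, "add"),      # boundary: not strictly above 10·E_T
            (15.0, "discard"),  # too distorted to be informative
        ],
    )
    def test_three_interval_partition(self, delta, verdict):
        cfg = EnergySelectorConfig(E_T=1.0)
        decision = energy_select(0.0, delta, cfg)
        assert decision.verdict == verdict
        assert decision.score == pytest.approx(delta)
        assert decision.threshold_used == 1.0

    def test_sign_independent(self):
        cfg = EnergySelectorConfig(E_T=1.0)
        assert energy_select(10.0, 5.0, cfg).verdict == "add"
        assert energy_select(5.0, 10.0, cfg).verdict == "add"

    def test_missing_reference_energy(self):
        with pytest.raises(ValueError, match="reference"):
            energy_select(None, 1.0, EnergySelectorConfig(E_T=1.0))

    def test_only_energy_selector_discards(self):
        with pytest.raises(ValueError, match="energy selector"):
            SelectorDecision(verdict="discard", score=1.0, threshold_used=1.0,
                             selector="similarity")


class TestSimilaritySelector:
    def _vec(self, x, y):
        v = np.array([x, y], float)
        from mlal.descriptors import DescriptorVector

        return DescriptorVector(values=v / np.linalg.norm(v))

    def test_identical_candidate_never_added(self):
        p = self._vec(1.0, 0.0)
        for k_T in (0.5, 0.999, 1.0):
            decision = similarity_select(p, [p, self._vec(0.6, 0.8)],
                                         SimilaritySelectorConfig(k_T=k_T))
            assert decision.verdict == "skip"
            assert decision.score == pytest.approx(1.0)

    def test_orthogonal_candidate_added(self):
        p = self._vec(1.0, 0.0)
        q = self._vec(0.0, 1.0)
        decision = similarity_select(p, [q], SimilaritySelectorConfig(k_T=0.9995))
        assert decision.verdict == "add"
        assert decision.score == 0.0

    def test_degenerate_threshold_one_adds_any_nonidentical(self):
        # k_T = 1 accepts everything not already in the set — no information gain
        p = self._vec(0.999, np.sqrt(1 - 0.999**2))
        q = self._vec(1.0, 0.0)
        decision = similarity_select(p, [q], SimilaritySelectorConfig(k_T=1.0))
        assert decision.verdict == "add"

    def test_monotone_in_threshold(self):
        # raising k_T can only flip skip→add, never add→skip
        p = self._vec(0.9, np.sqrt(0.19))
        training = [self._vec(1.0, 0.0)]
        verdicts = [
            similarity_select(p, training, SimilaritySelectorConfig(k_T=k_T)).verdict
            for k_T in (0.1, 0.4, 0.657, 0.9, 1.0)
        ]
        added = [v == "add" for v in verdicts]
        assert added == sorted(added)  # False...True, no add→skip flip

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimilaritySelectorConfig(k_T=0.0)
        with pytest.raises(ValueError):
            SimilaritySelectorConfig(k_T=1.5)


class TestLof:
    def test_uniform_grid_centre_is_exactly_one(self):
        grid = np.array([[i, j] for i in range(21) for j in range(21)], float)
        report = lof_profile(np.array([10.0, 10.0]), grid, k=8)
        assert report.lof == pytest.approx(1.0, abs=1e-12)

    def test_far_outlier_above_one(self):
        rng = np.random.default_rng(1)
        cloud = rng.normal(scale=0.5, size=(100, 2))
        assert lof_profile(np.array([10.0, 10.0]), cloud, k=10).lof > 1.0

    def test_dense_core_below_one(self):
        # concentric rings with geometrically growing radii: density decays
        # outward, so a point near the centre sits in a region denser than
        # its neighbours' — the textbook inlier case
        points, r = [], 0.5
        for i in range(8):
            angles = np.linspace(0, 2 * np.pi, 20, endpoint=False) + 0.1 * i
            points.append(np.stack([r * np.cos(angles), r * np.sin(angles)], axis=1))
            r *= 1.6
        cloud = np.vstack(points)
        assert lof_profile(np.array([0.05, 0.02]), cloud, k=10).lof < 1.0

    @pytest.mark.parametrize("k", [5, 10, 20])
    def test_matches_brute_force_oracle(self, k):
        rng = np.random.default_rng(k)
        X = rng.normal(size=(60, 3))
        o = rng.normal(size=3) * 1.5
        report = lof_profile(o, X, k)
        assert report.lof == pytest.approx(_brute_lof(o, X, k), abs=1e-10)

    def test_matches_sklearn(self):
        from sklearn.neighbors import LocalOutlierFactor

        rng = np.random.default_rng(7)
        X = rng.normal(size=(120, 4))
        mine = dataset_lofs(X, 10)
        sk = LocalOutlierFactor(n_neighbors=10).fit(X)
        np.testing.assert_allclose(mine, -sk.negative_outlier_factor_, atol=1e-9)

    def test_small_dataset_rejected(self):
        with pytest.raises(ValueError, match="k \\+ 1"):
            lof_profile(np.zeros(2), np.random.default_rng(0).normal(size=(5, 2)), k=10)

    def test_duplicates_collapsed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        dup = np.vstack([X, X[:5]])  # exact duplicates
        a = lof_profile(np.array([0.1, 0.1]), X, 5).lof
        b = lof_profile(np.array([0.1, 0.1]), dup, 5).lof
        assert a == pytest.approx(b, abs=1e-12)


class TestLofThreshold:
    def test_uniform_grid_threshold_is_one(self):
        grid = np.array([[i, j] for i in range(12) for j in range(12)], float)
        # every interior point has LOF ≈ 1; boundary points only slightly above
        assert lof_threshold(grid, k=8, percentile=80.0) == pytest.approx(1.0, abs=0.1)

    def test_lower_nearest_rank_convention(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 2))
        lofs = np.sort(dataset_lofs(X, 3))
        # 10 points at the 80th percentile → the 8th smallest value
        assert lof_threshold(X, k=3, percentile=80.0) == pytest.approx(lofs[7])

    def test_matches_brute_force_percentile(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(size=(40, 2)), rng.normal(size=(10, 2)) * 4 + 8])
        brute = sorted(_brute_member_lofs(X, 10))
        expected = brute[int(np.ceil(len(X) * 0.8)) - 1]
        assert lof_threshold(X, k=10, percentile=80.0) == pytest.approx(expected, abs=1e-10)


class TestDistanceSelector:
    def test_bulk_member_skipped_outlier_added(self):
        rng = np.random.default_rng(4)
        training = rng.normal(size=(60, 3))
        cfg = DistanceSelectorConfig(k=10)
        inlier = rng.normal(size=3) * 0.3
        assert distance_select(inlier, training, cfg).verdict == "skip"
        outlier = np.full(3, 12.0)
        decision = distance_select(outlier, training, cfg)
        assert decision.verdict == "add"
        assert decision.score > decision.threshold_used

    def test_decision_matches_compositional_oracle(self):
        rng = np.random.default_rng(6)
        training = rng.normal(size=(50, 2))
        cfg = DistanceSelectorConfig(k=7)
        for scale in (0.2, 3.0, 8.0):
            candidate = rng.normal(size=2) * scale
            decision = distance_select(candidate, training, cfg)
            expected = (
                "add"
                if lof_profile(candidate, training, 7).lof
                > lof_threshold(training, 7, 80.0)
                else "skip"
            )
            assert decision.verdict == expected

    def test_undersized_training_set_quotes_requirement(self):
        cfg = DistanceSelectorConfig(k=10, min_initial_size=15)
        with pytest.raises(ValueError, match="15"):
            distance_select(np.zeros(2), np.zeros((10, 2)), cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DistanceSelectorConfig(k=0)
        with pytest.raises(ValueError):
            DistanceSelectorConfig(k=5, min_initial_size=3)
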