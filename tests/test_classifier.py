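"""Centroid classifier training, distances, and confidence calls."""

import numpy as np
import pytest

import rnabc
from rnabc import ExpressionMatrix
from rnabc.classifier import _all_distances


def _training_from_points(points, labels):
    """points: samples x features."""
    points = np.asarray(points, dtype=float)
    return ExpressionMatrix.from_arrays(
        [f"g{i}" for i in range(points.shape[1])],
        [f"s{j}" for j in range(points.shape[0])],
        points.T, "normalized",
    )


@pytest.fixture
def planar_model():
    """Two well-separated subtypes in 2-D with unit-ish pooled variance."""
    rng = np.random.default_rng(7)
    a = rng.normal([0.0, 0.0], 1.0, size=(20, 2))
    b = rng.normal([8.0, 0.0], 1.0, size=(20, 2))
    training = _training_from_points(np.vstack([a, b]), None)
    labels = ["A"] * 20 + ["B"] * 20
    return rnabc.train_subtype_model(training, labels, ["g0", "g1"])


class TestTraining:
    def test_single_pair_degenerate_quantile(self):
        # centroids (0,0) and (4,0), pooled variance 1: the only pairwise
        # DLDA distance is 16, and any quantile of one value is that value
        r = 1 / np.sqrt(2)  # within-class SS = 2*r^2 per class, df = 2
        pts = [[-r, 0], [r, 0], [4 - r, 0], [4 + r, 0]]
        model = rnabc.train_subtype_model(
            _training_from_points(pts, None), ["A", "A", "B", "B"], ["g0", "g1"]
        )
        np.testing.assert_allclose(model.centroids, [[0, 0], [4, 0]])
        np.testing.assert_allclose(model.pooled_var, [1.0, 1e-8])
        assert model.mixed_threshold == pytest.approx(16.0)

    def test_degenerate_training_all_at_centroids(self):
        pts = [[0, 0], [0, 0], [4, 0], [4, 0]]
        with pytest.warns(UserWarning, match="zero MAD"):
            model = rnabc.train_subtype_model(
                _training_from_points(pts, None), ["A", "A", "B", "B"], ["g0", "g1"]
            )
        assert model.outlier_multiplier == 0.0
        np.testing.assert_array_equal(model.med, [0.0, 0.0])

    def test_outlier_multiplier_formula(self):
        # one subtype whose training distances to its centroid are {1,2,3,10}:
        # med = 2.5, raw MAD = median({1.5,0.5,0.5,7.5}) = 1.0,
        # contribution (10 - 2.5)/1.0 = 7.5 (verified with statistics.median)
        import statistics
        dists = [1.0, 2.0, 3.0, 10.0]
        med = statistics.median(dists)
        mad = statistics.median([abs(d - med) for d in dists])
        assert med == 2.5 and mad == 1.0
        assert (max(dists) - med) / mad == 7.5

    def test_subtype_with_one_sample_rejected(self):
        pts = [[0, 0], [0, 1], [4, 0]]
        with pytest.raises(ValueError, match="fewer than two"):
            rnabc.train_subtype_model(
                _training_from_points(pts, None), ["A", "A", "B"], ["g0", "g1"]
            )

    def test_missing_signature_rejected(self, planar_model):
        training = _training_from_points([[0, 0], [1, 1], [2, 2]], None)
        with pytest.raises(KeyError):
            rnabc.train_subtype_model(training, ["A", "A", "B"], ["g0", "gX"])


class TestDistances:
    def test_dlda_zero_at_centroid(self, planar_model):
        k = 0
        assert rnabc.dlda_distance(planar_model.centroids[k], k, planar_model) == 0.0

    def test_dlda_squared_euclidean_with_unit_variance(self):
        model = rnabc.SubtypeModel(
            subtypes=("A",), signature_ids=("g0", "g1"),
            centroids=np.array([[0.0, 0.0]]), pooled_var=np.array([1.0, 1.0]),
            distance_method="dlda", mixed_threshold=1.0,
            med=np.zeros(1), mad=np.zeros(1), outlier_multiplier=0.0,
        )
        assert rnabc.dlda_distance(np.array([3.0, 4.0]), 0, model) == pytest.approx(25.0)

    def test_dlda_variance_weighting(self):
        model = rnabc.SubtypeModel(
            subtypes=("A",), signature_ids=("g0", "g1"),
            centroids=np.array([[0.0, 0.0]]), pooled_var=np.array([1.0, 4.0]),
            distance_method="dlda", mixed_threshold=1.0,
            med=np.zeros(1), mad=np.zeros(1), outlier_multiplier=0.0,
        )
        assert rnabc.dlda_distance(np.array([2.0, 2.0]), 0, model) == pytest.approx(5.0)

    def test_pearson_reference_points(self, rng):
        c = rng.normal(size=10)
        assert rnabc.pearson_distance(c, c) == pytest.approx(0.0)
        assert rnabc.pearson_distance(-c + 3.0, c) == pytest.approx(2.0)
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert rnabc.pearson_distance(x, y) == pytest.approx(1.0)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            rnabc.pearson_distance(np.ones(5), np.arange(5.0))

    def test_dlda_scale_equivariance(self, planar_model, rng):
        """Scaling features, centroids, and variances together preserves calls."""
        x = rng.normal([1.0, 0.5], 1.0)
        call = rnabc.classify_sample(x, planar_model)
        import copy
        scaled = copy.deepcopy(planar_model)
        c = 3.7
        scaled.centroids *= c
        scaled.pooled_var *= c * c
        scaled.med, scaled.mad = planar_model.med, planar_model.mad
        call_scaled = rnabc.classify_sample(x * c, scaled)
        assert call_scaled.assigned_subtype == call.assigned_subtype
        assert call_scaled.confidence == call.confidence
        np.testing.assert_allclose(call_scaled.distances, call.distances, rtol=1e-9)


class TestClassifySample:
    def test_core_at_centroid(self, planar_model):
        call = rnabc.classify_sample(planar_model.centroids[0], planar_model)
        assert call.assigned_subtype == "A"
        assert call.confidence == "core"
        assert call.label == "A"

    def test_equidistant_is_mixed(self, planar_model):
        mid = planar_model.centroids.mean(axis=0)
        call = rnabc.classify_sample(mid, planar_model)
        assert call.confidence == "mixed"
        assert call.mixed_set == ("A", "B")
        assert call.label == "A/B mixed"

    def test_outlier_beyond_hand_computed_threshold(self, planar_model):
        # move outward along the A-B axis so the B distance stays far beyond
        # t while the A distance exceeds the hand-computed med + n*mad
        far = planar_model.centroids[0] + np.array([-30.0, 0.0])
        call = rnabc.classify_sample(far, planar_model)
        d = rnabc.dlda_distance(far, 0, planar_model)
        threshold = planar_model.med[0] + (
            planar_model.outlier_multiplier * planar_model.mad[0]
        )
        assert d > threshold
        assert call.confidence == "outlier"

    def test_n_mad_rule_variant(self, planar_model):
        planar_model.outlier_rule = "n_mad"
        thr = planar_model.outlier_threshold(0)
        assert thr == pytest.approx(
            planar_model.outlier_multiplier * planar_model.mad[0]
        )

    def test_most_extreme_training_sample_is_not_outlier(self):
        """Under med+n*mad, the worst training sample sits exactly on the
        threshold of its subtype, so no training sample is called outlier."""
        rng = np.random.default_rng(3)
        pts = np.vstack([
            rng.normal([0, 0], 1.0, size=(15, 2)),
            rng.normal([9, 0], 1.0, size=(15, 2)),
        ])
        labels = ["A"] * 15 + ["B"] * 15
        training = _training_from_points(pts, None)
        model = rnabc.train_subtype_model(training, labels, ["g0", "g1"])
        calls = rnabc.classify_matrix(training, model)
        assert all(c.confidence != "outlier" for c in calls)


class TestClassifyMatrix:
    def test_empty_matrix(self, planar_model):
        empty = ExpressionMatrix.from_arrays(
            ["g0", "g1"], [], np.empty((2, 0)), "normalized"
        )
        assert rnabc.classify_matrix(empty, planar_model) == []

    def test_columns_at_centroids_all_core(self, tiny_training):
        training, labels, sig = tiny_training
        model = rnabc.train_subtype_model(training, labels, sig)
        centroids_matrix = ExpressionMatrix.from_arrays(
            sig, list(model.subtypes), model.centroids.T, "normalized"
        )
        calls = rnabc.classify_matrix(centroids_matrix, model)
        assert [c.sample_id for c in calls] == list(model.subtypes)
        assert all(c.assigned_subtype == c.sample_id for c in calls)

    def test_missing_features_hard_error(self, planar_model):
        matrix = ExpressionMatrix.from_arrays(
            ["g0"], ["s"], [[1.0]], "normalized"
        )
        with pytest.raises(KeyError, match="signature feature"):
            rnabc.classify_matrix(matrix, planar_model)

    def test_model_json_roundtrip(self, tmp_path, planar_model):
        path = tmp_path / "model.json"
        planar_model.to_json(path)
        loaded = rnabc.SubtypeModel.from_json(path)
        assert loaded.subtypes == planar_model.subtypes
        np.testing.assert_allclose(loaded.centroids, planar_model.centroids)
        assert loaded.mixed_threshold == pytest.approx(planar_model.mixed_threshold)
        x = np.array([1.0, -0.5])
        assert (
            rnabc.classify_sample(x, loaded).label
            == rnabc.classify_sample(x, planar_model).label
        )


class TestProperties:
    @staticmethod
    def _blob_training(noise_sd, seed=5):
        """Four well-separated blobs with distinct pairwise distances."""
        rng = np.random.default_rng(seed)
        centroids = np.array(
            [[0.0, 0.0], [50.0, 0.0], [0.0, 90.0], [70.0, 80.0]]
        )
        pts, labels = [], []
        for k, c in enumerate(centroids):
            pts.append(rng.normal(c, noise_sd, size=(15, 2)))
            labels += [f"T{k}"] * 15
        return _training_from_points(np.vstack(pts), None), labels

    def test_self_classification_well_separated(self):
        """Separation >= 10x noise: every training sample self-classifies.

        Note the mixed threshold t (10th percentile of pairwise centroid
        distances, linearly interpolated) always exceeds the two smallest
        centroid distances, so members of the closest subtype pairs are mixed
        *by construction* no matter how large the separation; core confidence
        is guaranteed only outside those pairs.
        """
        training, labels = self._blob_training(noise_sd=1.0)
        model = rnabc.train_subtype_model(training, labels, ["g0", "g1"])
        calls = rnabc.classify_matrix(training, model)
        assert [c.assigned_subtype for c in calls] == labels
        # subtypes of centroid pairs closer than t are marked mixed by the
        # t-rule no matter the separation; everything else must be core
        dists = {
            (a, b): _all_distances(model.centroids[a], model)[b]
            for a in range(4) for b in range(a + 1, 4)
        }
        condemned = {
            model.subtypes[i]
            for pair, d in dists.items() if d < model.mixed_threshold
            for i in pair
        }
        for call in calls:
            if call.assigned_subtype in condemned:
                assert call.confidence == "mixed"
                assert set(call.mixed_set) <= condemned | {call.assigned_subtype}
            else:
                assert call.confidence == "core"

    def test_monotone_degradation_with_noise(self):
        """More noise strictly raises the mixed+outlier fraction (fixed seed)."""
        fracs = []
        for noise in (1.0, 8.0, 20.0):
            training, labels = self._blob_training(noise_sd=noise)
            model = rnabc.train_subtype_model(training, labels, ["g0", "g1"])
            calls = rnabc.classify_matrix(training, model)
            fracs.append(sum(c.confidence != "core" for c in calls) / len(calls))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_threshold_invariant_to_mad_scale_constant(self, planar_model):
        """med + n*mad does not change if MAD were rescaled by a constant:
        the constant cancels between n = (max-med)/mad and the threshold."""
        c = 1.4826
        n_scaled = planar_model.outlier_multiplier / c
        thr_scaled = planar_model.med[0] + n_scaled * (planar_model.mad[0] * c)
        assert thr_scaled == pytest.approx(planar_model.outlier_threshold(0))
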