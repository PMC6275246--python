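"""PCA projection into a frozen training space and concordance metrics."""

import numpy as np
import pytest

import rnabc
from rnabc import ExpressionMatrix
from rnabc.classifier import SubtypeCall


def _em(values, prefix="s", scale_tag="normalized"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix.from_arrays(
        [f"g{i}" for i in range(values.shape[0])],
        [f"{prefix}{j}" for j in range(values.shape[1])],
        values, scale_tag,
    )


class TestFitPca:
    def test_diagonal_cloud_pc1(self, rng):
        # points along y = x: PC1 loading proportional to (1,1)/sqrt(2),
        # sign-fixed positive
        t = rng.normal(size=200)
        pts = np.vstack([t, t + rng.normal(0, 0.01, size=200)])
        model = rnabc.fit_pca(_em(pts), scale_features=False)
        np.testing.assert_allclose(
            model.rotation[:, 0], [1 / np.sqrt(2)] * 2, atol=1e-2
        )

    def test_training_projection_reproduces_fit(self, rng):
        values = rng.normal(8, 2, size=(20, 15))
        m = _em(values)
        model = rnabc.fit_pca(m)
        scores = rnabc.project_samples(m, model, n_components=14)
        # scores reproduce the SVD fit: X_s = U S Vt and scores = X_s V
        xs = ((values.T - model.center) / model.scale)
        expected = xs @ model.rotation[:, :14]
        np.testing.assert_allclose(scores.to_numpy(), expected, atol=1e-8)

    def test_isotropic_cloud_equal_variance(self, rng):
        values = rng.normal(0, 1, size=(5, 2000))
        model = rnabc.fit_pca(_em(values), scale_features=False)
        ev = model.explained_variance
        assert ev.max() / ev.min() < 1.25  # sampling error only at n=2000

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="three"):
            rnabc.fit_pca(_em(rng.normal(size=(4, 2))))

    def test_zero_variance_feature_dropped_with_warning(self, rng):
        values = rng.normal(size=(4, 10))
        values[2] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = rnabc.fit_pca(_em(values))
        assert "g2" not in model.feature_ids

    def test_bit_identical_across_runs(self, rng):
        values = rng.normal(size=(12, 30))
        a = rnabc.fit_pca(_em(values))
        b = rnabc.fit_pca(_em(values.copy()))
        assert np.array_equal(a.rotation, b.rotation)
        test = _em(rng.normal(size=(12, 5)), prefix="t")
        np.testing.assert_array_equal(
            rnabc.project_samples(test, a).to_numpy(),
            rnabc.project_samples(test, b).to_numpy(),
        )


class TestProjectSamples:
    @pytest.fixture
    def fitted(self, rng):
        training = _em(rng.normal(8, 2, size=(10, 20)))
        return training, rnabc.fit_pca(training)

    def test_center_maps_to_origin(self, fitted):
        training, model = fitted
        col = model.center * model.scale * 0 + model.center  # = center
        m = ExpressionMatrix.from_arrays(
            list(model.feature_ids), ["c"], col[:, None], "normalized"
        )
        scores = rnabc.project_samples(m, model)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_symmetric_points_opposite_scores(self, fitted, rng):
        training, model = fitted
        delta = rng.normal(size=len(model.feature_ids))
        pair = np.column_stack([model.center + delta, model.center - delta])
        m = ExpressionMatrix.from_arrays(
            list(model.feature_ids), ["p", "q"], pair, "normalized"
        )
        scores = rnabc.project_samples(m, model).to_numpy()
        np.testing.assert_allclose(scores[0], -scores[1], atol=1e-10)

    def test_no_refit_on_new_test_sets(self, fitted, rng):
        training, model = fitted
        train_scores = rnabc.project_samples(training, model)
        _ = rnabc.project_samples(
            _em(rng.normal(8, 2, size=(10, 7)), prefix="x"), model
        )
        np.testing.assert_array_equal(
            rnabc.project_samples(training, model).to_numpy(),
            train_scores.to_numpy(),
        )

    def test_missing_features_rejected(self, fitted):
        _, model = fitted
        short = ExpressionMatrix.from_arrays(["g0"], ["s"], [[1.0]], "normalized")
        with pytest.raises(KeyError, match="missing"):
            rnabc.project_samples(short, model)


class TestMetrics:
    def test_r_squared_affine_exact(self, rng):
        x = rng.normal(size=50)
        assert rnabc.r_squared(x, x) == pytest.approx(1.0)
        assert rnabc.r_squared(x, 2 * x + 3) == pytest.approx(1.0)

    def test_r_squared_independent_near_zero(self, rng):
        x, y = rng.normal(size=10000), rng.normal(size=10000)
        assert rnabc.r_squared(x, y) == pytest.approx(0.0, abs=0.01)

    def test_r_squared_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            rnabc.r_squared(rng.normal(size=5), np.ones(5))

    def test_spearman_monotone_and_reversed(self, rng):
        x = rng.normal(size=30)
        assert rnabc.spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        rev = (-x)
        assert rnabc.spearman_rho(x, rev) == pytest.approx(-1.0)

    def test_spearman_ties_against_bruteforce_midranks(self, rng):
        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                ranks[order[i:j]] = (i + j - 1) / 2 + 1
                i = j
            return ranks

        x = rng.integers(0, 5, size=20).astype(float)  # plenty of ties
        y = rng.integers(0, 5, size=20).astype(float)
        expected = np.corrcoef(midranks(x), midranks(y))[0, 1]
        assert rnabc.spearman_rho(x, y) == pytest.approx(expected)

    def test_spearman_constant_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            rnabc.spearman_rho(np.ones(5), rng.normal(size=5))

    def test_affine_relation_makes_both_metrics_one(self, rng):
        x = rng.normal(size=100)
        y = 0.5 * x + 2.0
        assert rnabc.r_squared(x, y) == pytest.approx(1.0)
        assert rnabc.spearman_rho(x, y) == pytest.approx(1.0)


def _call(sample, subtype, confidence, mixed_set=None):
    subtypes = ("basL", "lumA", "lumB", "lumC", "mApo", "normL")
    return SubtypeCall(
        sample_id=sample, assigned_subtype=subtype, confidence=confidence,
        mixed_set=mixed_set or (subtype,), distances=np.zeros(6),
        subtypes=subtypes,
    )


class TestCompareCalls:
    def test_perfect_match(self):
        a = _call("s", "lumA", "core")
        assert rnabc.compare_calls(a, _call("s", "lumA", "core")) == "perfect_match"

    def test_core_vs_mixed_sharing_subtype(self):
        a = _call("s", "lumA", "core")
        b = _call("s", "lumB", "mixed", ("lumA", "lumB"))
        assert rnabc.compare_calls(a, b) == "confidence_mismatch"

    def test_mixed_sets_must_agree_for_perfect(self):
        a = _call("s", "lumA", "mixed", ("lumA", "lumB"))
        b = _call("s", "lumA", "mixed", ("lumA", "lumC"))
        assert rnabc.compare_calls(a, b) == "confidence_mismatch"
        c = _call("s", "lumA", "mixed", ("lumA", "lumB"))
        assert rnabc.compare_calls(a, c) == "perfect_match"

    def test_disjoint_subtypes_class_mismatch(self):
        a = _call("s", "lumA", "core")
        b = _call("s", "basL", "core")
        assert rnabc.compare_calls(a, b) == "class_mismatch"

    def test_core_vs_outlier_same_subtype(self):
        a = _call("s", "normL", "core")
        b = _call("s", "normL", "outlier")
        assert rnabc.compare_calls(a, b) == "confidence_mismatch"

    def test_symmetry(self):
        pairs = [
            (_call("s", "lumA", "core"), _call("s", "basL", "core")),
            (_call("s", "lumA", "core"), _call("s", "lumB", "mixed", ("lumA", "lumB"))),
            (_call("s", "lumA", "outlier"), _call("s", "lumA", "core")),
        ]
        for a, b in pairs:
            assert rnabc.compare_calls(a, b) == rnabc.compare_calls(b, a)

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sample IDs differ"):
            rnabc.compare_calls(_call("s1", "lumA", "core"), _call("s2", "lumA", "core"))
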