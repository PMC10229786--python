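import numpy as np
import pytest

from stdac.classify import (
    CLASSIFIER_KINDS,
    fit_stdac,
    fuse_score_matrix,
    fuse_scores,
    predict_scores,
    stdac_predict,
    train_branch,
)
from stdac.fbn import pearson_fbn


def separable_toy(n=30, d=6, gap=4.0, seed=0, n_classes=2):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        center = np.zeros(d)
        center[c % d] = gap * (c + 1)
        X.append(center + 0.2 * rng.standard_normal((n, d)))
        y += [f"class{c}"] * n
    return np.vstack(X), np.array(y)


def zscore_oracle(v):
    v = np.asarray(v, float)
    return (v - v.mean()) / v.std()


class TestTrainBranch:
    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_separable_training_accuracy(self, kind):
        X, y = separable_toy()
        model = train_branch(X, y, kind=kind, seed=0)
        scores = predict_scores(model, X)
        preds = [model.classes[i] for i in scores.argmax(axis=1)]
        assert np.mean(np.array(preds) == y) == 1.0

    def test_four_class_score_length(self):
        X, y = separable_toy(n=15, n_classes=4)
        model = train_branch(X, y, kind="svm", seed=0)
        assert predict_scores(model, X[:3]).shape == (3, 4)

    def test_probability_simplex(self):
        X, y = separable_toy()
        model = train_branch(X, y, kind="rf", seed=0)
        scores = predict_scores(model, X)
        assert np.all(scores >= 0)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-8)

    def test_deterministic_given_seed(self):
        X, y = separable_toy(seed=5)
        s1 = predict_scores(train_branch(X, y, "svm", seed=9), X)
        s2 = predict_scores(train_branch(X, y, "svm", seed=9), X)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_fatal(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError, match="single class"):
            train_branch(X, ["a"] * 10, "svm")

    def test_dimension_mismatch_fatal(self):
        X, y = separable_toy()
        model = train_branch(X, y, "svm")
        with pytest.raises(ValueError, match="dimensionality"):
            predict_scores(model, X[:, :3])

    def test_label_permutation_permutes_scores(self):
        # renaming classes reorders the score columns consistently
        X, y = separable_toy(seed=2)
        m1 = train_branch(X, y, "rf", seed=0)
        renamed = np.where(y == "class0", "zzz", "aaa")
        m2 = train_branch(X, renamed, "rf", seed=0)
        s1 = predict_scores(m1, X)  # columns: class0, class1
        s2 = predict_scores(m2, X)  # columns: aaa(=class1), zzz(=class0)
        np.testing.assert_allclose(s1[:, 0], s2[:, 1], atol=1e-12)
        np.testing.assert_allclose(s1[:, 1], s2[:, 0], atol=1e-12)


class TestFuseScores:
    def test_one_hot_outer_product_single_cell(self):
        omega_raw = np.outer([1, 0, 0], [0, 1, 0]).ravel()
        assert omega_raw[1] == 1 and omega_raw.sum() == 1
        omega = fuse_scores([1, 0, 0], [0, 1, 0])
        np.testing.assert_allclose(omega, zscore_oracle(omega_raw), atol=1e-12)

    def test_hand_computed_two_class_example(self):
        pre = np.array([0.48, 0.32, 0.12, 0.08])
        omega = fuse_scores([0.8, 0.2], [0.6, 0.4])
        np.testing.assert_allclose(omega, zscore_oracle(pre), atol=1e-12)

    def test_four_class_length_sixteen(self):
        omega = fuse_scores(np.full(4, 0.25) + [0.1, -0.1, 0.05, -0.05],
                            [0.7, 0.1, 0.1, 0.1])
        assert omega.shape == (16,)

    def test_normalization_invariants_random_pairs(self, rng):
        for _ in range(200):
            c = rng.integers(2, 6)
            sp = rng.dirichlet(np.ones(c))
            te = rng.dirichlet(np.ones(c))
            omega = fuse_scores(sp, te)
            assert abs(omega.mean()) < 1e-8
            assert abs(omega.std() - 1) < 1e-8

    def test_rank_one_structure(self, rng):
        sp = rng.dirichlet(np.ones(3))
        te = rng.dirichlet(np.ones(3))
        pre = np.outer(sp, te)
        np.testing.assert_allclose(
            fuse_scores(sp, te).reshape(3, 3), zscore_oracle(pre.ravel()).reshape(3, 3)
        )
        assert np.linalg.matrix_rank(pre) == 1

    def test_degenerate_constant_product_gives_zeros(self):
        omega = fuse_scores([0.5, 0.5], [0.5, 0.5])
        np.testing.assert_array_equal(omega, np.zeros(4))

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError, match="lengths differ"):
            fuse_scores([0.5, 0.5], [0.2, 0.3, 0.5])


class TestEndToEnd:
    def _cohort_features(self, tiny_cohort):
        subjects, geometry, _ = tiny_cohort
        X = np.vstack([pearson_fbn(s.signals).features for s in subjects])
        y = [s.label for s in subjects]
        return subjects, X, y

    def test_fusion_not_worse_than_branches_on_training_data(self, tiny_cohort):
        subjects, X, y = self._cohort_features(tiny_cohort)
        model = fit_stdac(X, y, X, y, X, y, kind="svm", seed=0)
        fused = fuse_score_matrix(
            predict_scores(model.spatial, X), predict_scores(model.temporal, X)
        )
        fusion_preds = [
            model.classes[i] for i in predict_scores(model.fusion, fused).argmax(axis=1)
        ]
        branch_accs = []
        for branch in (model.spatial, model.temporal):
            preds = [branch.classes[i] for i in predict_scores(branch, X).argmax(axis=1)]
            branch_accs.append(np.mean(np.array(preds) == np.array(y)))
        assert np.mean(np.array(fusion_preds) == np.array(y)) >= max(branch_accs) - 1e-9

    def test_pipeline_equals_manual_composition(self, tiny_cohort):
        subjects, X, y = self._cohort_features(tiny_cohort)
        model = fit_stdac(X, y, X, y, X, y, kind="rf", seed=1)
        subject = subjects[0]
        label, scores = stdac_predict(model, subject)
        feats = pearson_fbn(subject.signals).features[None, :]
        omega = fuse_score_matrix(
            predict_scores(model.spatial, feats),
            predict_scores(model.temporal, feats),
        )
        manual = predict_scores(model.fusion, omega)[0]
        np.testing.assert_array_equal(scores, manual)
        assert label == model.classes[int(np.argmax(manual))]
        assert label in {s.label for s in subjects}

    def test_degenerate_identical_branches_no_crash(self):
        # both branches emit the same near-constant scores; fusion still trains
        X, y = separable_toy(n=12, gap=0.0, seed=4)  # no signal at all
        model = fit_stdac(X, y, X, y, X, y, kind="rf", seed=0)
        scores = predict_scores(model.fusion, np.zeros((1, 4)))[0]
        label = model.classes[int(np.argmax(scores))]
        assert label in model.classes and np.isfinite(scores).all()
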