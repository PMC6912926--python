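"""RBF-SVM training, scoring, and the intensity z-transform."""

import numpy as np
import pytest
from sklearn.svm import SVC

from finsex import svm as fsvm
from finsex.features import extract_fin_features


class TestGaussianKernel:
    def test_self_similarity_and_symmetry(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        assert fsvm.gaussian_kernel(x, x, 0.7) == 1.0
        assert fsvm.gaussian_kernel(x, y, 0.7) == fsvm.gaussian_kernel(y, x, 0.7)
        assert 0 < fsvm.gaussian_kernel(x, y, 0.7) <= 1

    def test_hand_evaluated_value(self):
        assert np.isclose(
            fsvm.gaussian_kernel([0.0, 0.0], [1.0, 1.0], 0.5), np.exp(-1.0), atol=1e-12
        )

    def test_length_mismatch_and_bad_gamma(self):
        with pytest.raises(ValueError, match="mismatch"):
            fsvm.gaussian_kernel([0.0], [0.0, 1.0], 1.0)
        with pytest.raises(ValueError, match="gamma"):
            fsvm.gaussian_kernel([0.0], [1.0], 0.0)


def _separable_toy(n=10):
    """Two single-bin histogram classes: trivially separable."""
    X = np.zeros((2 * n, 6))
    X[:n, 0] = 1.0   # class F
    X[n:, 3] = 1.0   # class M
    y = np.array(["F"] * n + ["M"] * n)
    return X, y


class TestTrain:
    def test_separable_toy_is_perfectly_classified(self):
        X, y = _separable_toy()
        model = fsvm.train(X, y, gamma=1.0, C=10.0)
        d = model.decision_values(X)
        assert np.all(np.where(d > 0, "M", "F") == y)

    def test_single_class_rejected(self):
        X, _ = _separable_toy()
        with pytest.raises(ValueError, match="both classes"):
            fsvm.train(X, ["M"] * len(X))
        with pytest.raises(ValueError, match="2 samples"):
            fsvm.train(X[:3], ["M", "M", "F"])

    def test_training_is_deterministic(self, svm_cohort):
        _, X, y = extract_fin_features(svm_cohort.samples[30:70])
        m1 = fsvm.train(X, y)
        m2 = fsvm.train(X, y)
        assert np.array_equal(m1.support_vectors, m2.support_vectors)
        assert np.array_equal(m1.dual_weights, m2.dual_weights)
        assert m1.bias == m2.bias

    def test_label_shuffle_control_near_chance(self, svm_cohort, rng):
        """Permuting labels destroys the signal: CV accuracy ~ 0.5."""
        _, X, y = extract_fin_features(svm_cohort.samples[:100])
        accs = []
        for _ in range(10):
            accs.append(fsvm.cross_validated_accuracy(X, rng.permutation(y), seed=0))
        mean_acc = np.mean(accs)
        assert abs(mean_acc - 0.5) < 0.12


class TestScore:
    def test_decision_matches_brute_force_kernel_sum_and_sklearn(self, svm_cohort):
        ids, X, y = extract_fin_features(svm_cohort.samples[:60])
        model = fsvm.train(X, y)
        svc = SVC(kernel="rbf", gamma=model.gamma, C=model.regularization)
        svc.fit(X, y)
        for x in X[:8]:
            ours = model.decision_values(x)[0]
            brute = sum(
                w * fsvm.gaussian_kernel(sv, x, model.gamma)
                for w, sv in zip(model.dual_weights, model.support_vectors)
            ) + model.bias
            assert abs(ours - brute) < 1e-8
            assert abs(ours - svc.decision_function(x.reshape(1, -1))[0]) < 1e-8

    def test_midpoint_tie_classified_female(self):
        # two symmetric single-support-vector classes; midpoint has d = 0
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        model = fsvm.SvmModel(
            support_vectors=X,
            dual_weights=np.array([-1.0, 1.0]),
            bias=0.0,
            gamma=0.5,
            regularization=1.0,
        )
        s = fsvm.score(model, np.array([1.0, 0.0]), sample_id="mid")
        assert s.d == 0.0
        assert s.predicted_sex == "F"

    def test_signs_follow_labels_in_separable_case(self):
        X, y = _separable_toy()
        model = fsvm.train(X, y, gamma=1.0, C=10.0)
        scores = fsvm.score_cohort(model, X, [f"s{i}" for i in range(len(X))])
        assert all(
            (sc.predicted_sex == "M") == (lbl == "M") for sc, lbl in zip(scores, y)
        )
        for sc in scores:
            assert sc.s_female == -sc.s_male
            assert sc.d == sc.s_male  # the signed decision value itself

    def test_dimension_mismatch_rejected(self):
        X, y = _separable_toy()
        model = fsvm.train(X, y, gamma=1.0)
        with pytest.raises(ValueError, match="dimension"):
            model.decision_values(np.zeros(5))

    def test_json_round_trip_preserves_decisions(self, tmp_path):
        X, y = _separable_toy()
        model = fsvm.train(X, y, gamma=2.0, C=3.0)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = fsvm.SvmModel.from_json(path)
        assert np.allclose(model.decision_values(X), loaded.decision_values(X))
        assert loaded.regularization == 3.0


class TestIntensityScores:
    def _scores(self, d):
        return [
            fsvm.SexScore(id=str(i), s_male=v, s_female=-v, d=v,
                          predicted_sex="M" if v > 0 else "F")
            for i, v in enumerate(d)
        ]

    def test_closed_form_on_1_2_3(self):
        z = [s.z for s in fsvm.intensity_scores(self._scores([1.0, 2.0, 3.0]))]
        assert np.allclose(z, [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_population_moments_and_order(self, rng):
        d = rng.normal(size=40)
        scored = fsvm.intensity_scores(self._scores(d))
        z = np.array([s.z for s in scored])
        assert abs(z.mean()) < 1e-12
        assert np.isclose(z.std(), 1.0)
        assert np.array_equal(np.argsort(z), np.argsort(d))

    def test_location_invariance(self, rng):
        d = rng.normal(size=15)
        z1 = [s.z for s in fsvm.intensity_scores(self._scores(d))]
        z2 = [s.z for s in fsvm.intensity_scores(self._scores(d + 7.5))]
        assert np.allclose(z1, z2)

    def test_sample_denominator_option(self):
        scored = fsvm.intensity_scores(self._scores([1.0, 2.0, 3.0]), ddof=1)
        assert np.isclose(scored[2].z, 1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fsvm.intensity_scores(self._scores([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="at least 2"):
            fsvm.intensity_scores(self._scores([1.0]))
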