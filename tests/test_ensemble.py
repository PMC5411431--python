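"""Resample plans, L x M fitting and posterior averaging."""
from __future__ import annotations

import numpy as np
import pytest

import errpdecode as ed
from errpdecode.ensemble import (
    LEARNER_NAMES,
    EnsembleModel,
    ResamplePlan,
    Standardizer,
)


@pytest.fixture(scope="module")
def clouds():
    """Two well-separated Gaussian clouds (4 SD apart)."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, (100, 5)), rng.normal(4, 1, (100, 5))])
    y = np.r_[np.zeros(100, int), np.ones(100, int)]
    return ed.LabeledFeatureSet(X, y)


class TestResamplePlan:
    def test_stratified_kfold_sizes(self):
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        plan = ed.build_resamples(y, k=10, seed=0)
        assert plan.M == 10
        assert all(idx.size == 90 for idx in plan.indices)
        for idx in plan.indices:
            assert np.bincount(y[idx], minlength=2).min() == 45

    def test_minimal_balanced_case(self):
        y = np.array([0, 1, 0, 1])
        plan = ed.build_resamples(y, k=2, seed=1)
        for idx in plan.indices:
            assert sorted(y[idx]) == [0, 1]

    def test_deterministic_given_seed(self):
        y = np.tile([0, 1], 50)
        a = ed.build_resamples(y, k=10, seed=5)
        b = ed.build_resamples(y, k=10, seed=5)
        assert all(np.array_equal(i, j)
                   for i, j in zip(a.indices, b.indices))

    def test_with_replacement_variant(self):
        y = np.tile([0, 1], 50)
        plan = ed.build_resamples(y, k=10, seed=2, with_replacement=True)
        assert plan.with_replacement
        assert all(idx.size == 90 for idx in plan.indices)
        assert any(np.unique(idx).size < idx.size for idx in plan.indices)

    def test_small_minority_rejected(self):
        y = np.r_[np.zeros(97, int), np.ones(3, int)]
        with pytest.raises(ValueError):
            ed.build_resamples(y, k=10)


class TestFitEnsemble:
    def test_l_times_m_estimators(self, clouds):
        model = ed.fit_ensemble(clouds, seed=0)
        assert model.n_estimators == 4 * 10
        assert model.learner_names == LEARNER_NAMES

    def test_separable_clouds_high_accuracy(self, clouds):
        model = ed.fit_ensemble(clouds, seed=0)
        p = ed.ensemble_posterior(model, clouds.X)
        acc = (ed.classify(p) == clouds.y).mean()
        assert acc >= 0.95

    def test_refit_is_deterministic(self, clouds):
        p1 = ed.ensemble_posterior(ed.fit_ensemble(clouds, seed=3), clouds.X)
        p2 = ed.ensemble_posterior(ed.fit_ensemble(clouds, seed=3), clouds.X)
        assert np.array_equal(p1, p2)

    def test_row_permutation_invariance(self, clouds):
        """Shuffling training-row order (with the resample index sets
        remapped accordingly) leaves predictions unchanged."""
        rng = np.random.default_rng(9)
        perm = rng.permutation(clouds.n)
        plan = ed.build_resamples(clouds.y, k=10, seed=4)
        inverse = np.empty_like(perm)
        inverse[perm] = np.arange(clouds.n)
        shuffled = ed.LabeledFeatureSet(clouds.X[perm], clouds.y[perm])
        plan_shuffled = ResamplePlan(
            indices=tuple(np.sort(inverse[idx]) for idx in plan.indices),
            k=plan.k, seed=plan.seed)
        p1 = ed.ensemble_posterior(ed.fit_ensemble(clouds, plan), clouds.X)
        p2 = ed.ensemble_posterior(ed.fit_ensemble(shuffled, plan_shuffled),
                                   clouds.X)
        assert np.allclose(p1, p2, atol=1e-6)

    def test_degenerate_labels_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            ed.LabeledFeatureSet(X, np.zeros(10, int))


class TestPosterior:
    class _Stub:
        classes_ = np.array([0, 1])

        def __init__(self, p):
            self.p = p

        def predict_proba(self, X):
            return np.tile([1 - self.p, self.p], (len(X), 1))

    def _stub_model(self, posteriors):
        ests = [[self._Stub(p)] for p in posteriors]
        return EnsembleModel(
            learner_names=tuple(f"s{i}" for i in range(len(posteriors))),
            estimators=ests, scaler=None,
            plan=ResamplePlan(indices=(np.arange(2),), k=2, seed=0), d=3)

    def test_average_of_stub_posteriors(self):
        model = self._stub_model([0.2, 0.4, 0.6, 0.8])
        assert ed.ensemble_posterior(model, np.zeros((1, 3)))[0] == \
            pytest.approx(0.5)

    def test_single_estimator_passthrough(self):
        model = self._stub_model([0.7])
        assert ed.ensemble_posterior(model, np.zeros((1, 3)))[0] == \
            pytest.approx(0.7)

    def test_posteriors_are_proper(self, clouds):
        model = ed.fit_ensemble(clouds, seed=1)
        p = ed.ensemble_posterior(model, clouds.X)
        assert np.all((p >= 0) & (p <= 1))
        # complement symmetry: P(error) + P(no-error) = 1 by construction
        # of each learner's two-class posterior

    def test_dimension_mismatch_rejected(self, clouds):
        model = ed.fit_ensemble(clouds, seed=1)
        with pytest.raises(ValueError):
            ed.ensemble_posterior(model, np.zeros((2, 3)))


class TestClassify:
    @pytest.mark.parametrize("p, expected", [(0.7, 1), (0.5, 1), (0.49, 0)])
    def test_threshold_rule(self, p, expected):
        assert ed.classify(p) == expected

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            ed.classify(0.5, threshold=0.0)


class TestStandardizer:
    def test_zero_variance_guard(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        sc = Standardizer.fit(X)
        Xs = sc.transform(X)
        assert np.allclose(Xs[:, 1], 0.0)
        assert np.isfinite(Xs).all()


def test_model_roundtrip(tmp_path, clouds):
    model = ed.fit_ensemble(clouds, seed=2,
                            selected_channels=("Cz", "Fz"))
    path = tmp_path / "model.joblib"
    ed.save_model(model, path)
    back = ed.load_model(path)
    assert back.selected_channels == ("Cz", "Fz")
    assert np.array_equal(ed.ensemble_posterior(back, clouds.X),
                          ed.ensemble_posterior(model, clouds.X))
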