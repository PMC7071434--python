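"""MLR, ANN, and ensemble reconstruction estimators."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import r2_score

from ecgrecon.grid import ElectrodeCombination, compute_chest_leads
from ecgrecon.models import (
    ANNReconstructor,
    EnsembleReconstructor,
    MLRReconstructor,
    model_from_json,
    model_to_json,
)
from ecgrecon.preprocess import derive_12lead


def _linear_data(n=2000, noise=0.0, seed=0, n_out=12):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    A = rng.normal(size=(3, n_out))
    c = rng.normal(size=n_out)
    Y = X @ A + c + noise * rng.normal(size=(n, n_out))
    return X, Y, A, c


class TestMLR:
    def test_recovers_known_affine_map(self):
        X, Y, A, c = _linear_data(noise=0.0)
        # feed pre-standardized inputs so coefficients are directly comparable
        Xs = (X - X.mean(0)) / X.std(0)
        Ys = Xs @ A + c
        m = MLRReconstructor(scale_inputs=False).fit(Xs, Ys)
        assert np.max(np.abs(m.coef_ - A.T)) < 1e-8
        assert np.max(np.abs(m.intercept_ - c)) < 1e-8
        assert m.b_.shape == (12, 4)

    def test_residuals_orthogonal_to_design(self):
        X, Y, *_ = _linear_data(noise=0.5, seed=3)
        m = MLRReconstructor().fit(X, Y)
        resid = Y - m.predict(X)
        Xs = (X - m.x_mean_) / m.x_scale_
        assert np.max(np.abs(Xs.T @ resid)) < 1e-6
        assert np.max(np.abs(resid.sum(axis=0))) < 1e-6

    def test_pure_noise_coefficients_shrink_to_zero(self):
        """Targets independent of inputs: coefficients are O(sd/sqrt(n))
        and out-of-sample R^2 is ~0."""
        rng = np.random.default_rng(11)
        n = 40000
        X = rng.normal(size=(n, 3))
        Y = rng.normal(size=(n, 12))
        m = MLRReconstructor().fit(X, Y)
        assert np.max(np.abs(m.coef_)) < 5.0 / np.sqrt(n)
        X2 = rng.normal(size=(5000, 3))
        Y2 = rng.normal(size=(5000, 12))
        assert abs(r2_score(Y2, m.predict(X2))) < 0.02

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        X[:, 2] = X[:, 0] + X[:, 1]  # linearly dependent chest leads
        with pytest.raises(ValueError, match="rank"):
            MLRReconstructor().fit(X, rng.normal(size=(100, 12)))

    def test_bias_only_model_predicts_constant(self):
        m = MLRReconstructor(scale_inputs=False)
        m.coef_ = np.zeros((12, 3))
        m.intercept_ = np.arange(12.0)
        m.x_mean_ = np.zeros(3)
        m.x_scale_ = np.ones(3)
        m.n_features_in_ = 3
        out = m.predict(np.random.default_rng(0).normal(size=(50, 3)))
        assert np.allclose(out, np.tile(np.arange(12.0), (50, 1)))

    def test_reference_electrode_choice_does_not_change_predictions(
        self, single_dipole_recording
    ):
        """Any fixed chest-lead reference spans the same affine space, so
        MLR predictions (hence CC/RMSE) are reference-invariant."""
        rec = single_dipole_recording
        leads = derive_12lead(rec).matrix().T
        combo = ElectrodeCombination((7, 9, 17, 19))
        cl_star = compute_chest_leads(rec.chest, combo).cl  # ref = id 7
        # alternative: reference the highest id instead
        alt = np.stack([rec.chest[i - 1] - rec.chest[19 - 1] for i in (7, 9, 17)])
        p1 = MLRReconstructor().fit(cl_star.T, leads).predict(cl_star.T)
        p2 = MLRReconstructor().fit(alt.T, leads).predict(alt.T)
        scale = np.max(np.abs(leads))
        assert np.max(np.abs(p1 - p2)) < 1e-8 * scale


class TestANN:
    def test_analytic_gradient_matches_finite_differences(self):
        """Backprop gradient oracle: central finite differences."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 12))
        for activation in ("linear", "softmax"):
            m = ANNReconstructor(output_activation=activation, seed=0)
            shapes = m._shapes(3, 12)
            theta = rng.normal(scale=0.3, size=sum(int(np.prod(s)) for s in shapes))
            loss, grad = m._loss_grad(theta, X, Y, shapes)
            eps = 1e-6
            for k in rng.choice(theta.size, size=12, replace=False):
                tp, tm = theta.copy(), theta.copy()
                tp[k] += eps
                tm[k] -= eps
                num = (
                    m._loss_grad(tp, X, Y, shapes)[0]
                    - m._loss_grad(tm, X, Y, shapes)[0]
                ) / (2 * eps)
                assert num == pytest.approx(grad[k], rel=1e-4, abs=1e-9)

    def test_memorizes_affine_targets(self):
        X, Y, *_ = _linear_data(n=1500, noise=0.0, seed=5)
        m = ANNReconstructor(seed=1, max_iter=1000).fit(X, Y)
        assert r2_score(Y, m.predict(X)) >= 0.99

    def test_same_seed_identical_predictions(self):
        X, Y, *_ = _linear_data(n=600, noise=0.2, seed=6)
        a = ANNReconstructor(seed=7, max_iter=100).fit(X, Y)
        b = ANNReconstructor(seed=7, max_iter=100).fit(X, Y)
        assert np.array_equal(a.predict(X), b.predict(X))

    def test_different_seeds_differ(self):
        X, Y, *_ = _linear_data(n=600, noise=0.2, seed=6)
        a = ANNReconstructor(seed=1, max_iter=60).fit(X, Y)
        b = ANNReconstructor(seed=2, max_iter=60).fit(X, Y)
        assert not np.allclose(a.W1_, b.W1_)

    def test_loss_history_non_increasing(self):
        X, Y, *_ = _linear_data(n=800, noise=0.3, seed=8)
        m = ANNReconstructor(seed=3, max_iter=150).fit(X, Y)
        assert np.all(np.diff(m.loss_history_) <= 1e-9)

    def test_not_worse_than_mlr_on_linear_train_data(self):
        X, Y, *_ = _linear_data(n=3000, noise=0.3, seed=9)
        mlr_mse = np.mean((MLRReconstructor().fit(X, Y).predict(X) - Y) ** 2)
        ann_mse = np.mean(
            (ANNReconstructor(seed=2, max_iter=500).fit(X, Y).predict(X) - Y) ** 2
        )
        assert ann_mse <= mlr_mse * 1.02

    def test_matches_sklearn_mlp_on_linear_data(self):
        """Independent cross-check: sklearn's MLP with the same topology
        also solves the linear task; both reach train R^2 > 0.99."""
        from sklearn.neural_network import MLPRegressor

        X, Y, *_ = _linear_data(n=1200, noise=0.0, seed=10)
        ours = ANNReconstructor(seed=1, max_iter=1000).fit(X, Y)
        theirs = MLPRegressor(
            hidden_layer_sizes=(6,), activation="logistic", solver="lbfgs",
            max_iter=2000, random_state=1,
        ).fit(X, Y)
        assert r2_score(Y, ours.predict(X)) > 0.99
        assert r2_score(Y, theirs.predict(X)) > 0.99

    def test_softmax_output_mode_runs_and_normalizes(self):
        X, Y, *_ = _linear_data(n=400, seed=12)
        m = ANNReconstructor(output_activation="softmax", seed=0, max_iter=50).fit(X, Y)
        Xs = (X - m.x_mean_) / m.x_scale_
        probs = m._forward_standardized(Xs)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.all(probs >= 0)

    def test_invalid_activation_rejected(self):
        X, Y, *_ = _linear_data(n=100)
        with pytest.raises(ValueError):
            ANNReconstructor(output_activation="relu").fit(X, Y)

    def test_sklearn_clone_compatible(self):
        m = ANNReconstructor(seed=5, hidden_units=4)
        c = clone(m)
        assert c.get_params() == m.get_params()


class TestEnsemble:
    def test_prediction_is_mean_of_members(self):
        X, Y, *_ = _linear_data(n=500, noise=0.2, seed=13)
        ens = EnsembleReconstructor(seeds=(1, 2, 3), max_iter=60).fit(X, Y)
        member_mean = np.mean([m.predict(X) for m in ens.members_], axis=0)
        assert np.allclose(ens.predict(X), member_mean)

    def test_repeated_seed_equals_single_member(self):
        X, Y, *_ = _linear_data(n=400, noise=0.2, seed=14)
        ens = EnsembleReconstructor(
            seeds=(9, 9), max_iter=60, require_distinct_seeds=False
        ).fit(X, Y)
        single = ANNReconstructor(seed=9, max_iter=60).fit(X, Y)
        assert np.allclose(ens.predict(X), single.predict(X))

    def test_distinct_seeds_enforced_by_default(self):
        X, Y, *_ = _linear_data(n=400)
        with pytest.raises(ValueError, match="distinct"):
            EnsembleReconstructor(seeds=(1, 1, 2, 3, 4)).fit(X, Y)

    def test_ensemble_mse_never_exceeds_mean_member_mse(self):
        X, Y, *_ = _linear_data(n=1200, noise=0.5, seed=15)
        Xt, Yt, *_ = _linear_data(n=800, noise=0.5, seed=16)
        ens = EnsembleReconstructor(seeds=(1, 2, 3, 4, 5), max_iter=60).fit(X, Y)
        preds = np.stack([m.predict(Xt) for m in ens.members_])
        member_mse = np.mean((preds - Yt) ** 2, axis=(1, 2))
        ens_mse = np.mean((ens.predict(Xt) - Yt) ** 2)
        assert ens_mse <= member_mse.mean() + 1e-12

    def test_ensembling_reduces_seed_to_seed_variance(self):
        """20 seed draws: variance of 4 disjoint 5-member ensemble
        predictions is below the variance of the 20 single models."""
        X, Y, *_ = _linear_data(n=600, noise=0.8, seed=17)
        Xt = np.random.default_rng(18).normal(size=(100, 3))
        singles = [
            ANNReconstructor(seed=s, max_iter=40).fit(X, Y).predict(Xt)
            for s in range(20)
        ]
        singles = np.stack(singles)
        ensembles = np.stack(
            [singles[5 * k : 5 * (k + 1)].mean(axis=0) for k in range(4)]
        )
        var_single = singles.var(axis=0).mean()
        var_ens = ensembles.var(axis=0).mean()
        assert var_ens < var_single


class TestSerialization:
    @pytest.mark.parametrize("kind", ["mlr", "ann", "ensemble"])
    def test_round_trip_preserves_predictions(self, kind):
        X, Y, *_ = _linear_data(n=400, noise=0.2, seed=19)
        if kind == "mlr":
            model = MLRReconstructor().fit(X, Y)
        elif kind == "ann":
            model = ANNReconstructor(seed=3, max_iter=40).fit(X, Y)
        else:
            model = EnsembleReconstructor(seeds=(1, 2, 3), max_iter=40).fit(X, Y)
        restored = model_from_json(model_to_json(model))
        assert np.allclose(restored.predict(X), model.predict(X), atol=1e-12)
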