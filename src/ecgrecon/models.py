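"""Universal 12-lead reconstruction models: MLR and a 3-6-12 feedforward ANN.

Both estimators map three bipolar chest leads (uV) to the 12 standard leads
(uV) with a single transformation fitted on data pooled across subjects —
a *universal* coefficient, applied to unseen subjects without per-person
calibration. They follow the scikit-learn estimator contract
(``fit(X, y)`` / ``predict(X)`` on sample-major arrays, ``get_params`` /
``set_params``, fitted attributes with trailing underscores) and compose
with sklearn pipelines and model selection.

* :class:`MLRReconstructor` — per-lead multiple linear regression
  ``y = b X + e`` solved by least squares; inputs are standardized with
  train statistics, targets stay in uV, so the 12 x 4 coefficient matrix
  (3 weights + bias per lead) acts on standardized chest leads.
* :class:`ANNReconstructor` — one hidden layer of 6 logistic-sigmoid units
  between a 3-unit input and 12-unit output layer, trained full-batch with
  L-BFGS on mean-squared error. Targets are standardized during training and
  predictions inverted back to uV. The output activation is linear by
  default; a softmax mode exists for parity with toolbox conventions, but a
  softmax constrains outputs to a positive simplex and cannot represent
  signed ECG voltages, so it is not the default.
* :class:`EnsembleReconstructor` — five ANNs from distinct random
  initializations, predictions averaged pointwise. Gradient training lands
  in different local minima per seed; averaging reduces that variance and,
  by convexity of squared error, the ensemble's MSE never exceeds the mean
  of its members'.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MLRReconstructor",
    "ANNReconstructor",
    "EnsembleReconstructor",
    "fit_mlr",
    "fit_ann",
    "fit_ensemble",
    "predict",
    "model_to_json",
    "model_from_json",
]

DEFAULT_ENSEMBLE_SEEDS = (101, 102, 103, 104, 105)


def _validate_xy(X, y, min_rank: int = 4):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 2:
        raise ValueError("X and y must be 2-D (n_samples, n_features/leads)")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of samples")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more samples than features plus bias")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain non-finite values")
    design = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(design) < min(min_rank, design.shape[1]):
        raise ValueError(
            "rank-deficient input: chest leads are linearly dependent"
        )
    return X, y


def _fit_scaler(A: np.ndarray, allow_constant: bool = False):
    mean = A.mean(axis=0)
    sd = A.std(axis=0)
    if np.any(sd <= 0):
        if not allow_constant:
            raise ValueError("constant input channel: cannot standardize")
        sd = np.where(sd <= 0, 1.0, sd)
    return mean, sd


class MLRReconstructor(BaseEstimator, RegressorMixin):
    """Least-squares multiple linear regression from 3 chest leads to 12 leads.

    Parameters
    ----------
    scale_inputs : bool, default True
        Standardize inputs with train statistics before regression. Disable
        when the caller already feeds standardized chest leads.

    Attributes
    ----------
    coef_ : (n_leads, n_features) weights on (standardized) inputs.
    intercept_ : (n_leads,) bias terms, uV.
    b_ : (n_leads, n_features + 1) full coefficient matrix, bias first.
    x_mean_, x_scale_ : train input statistics (identity if not scaling).
    """

    def __init__(self, scale_inputs: bool = True):
        self.scale_inputs = scale_inputs

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        if self.scale_inputs:
            self.x_mean_, self.x_scale_ = _fit_scaler(X)
        else:
            self.x_mean_ = np.zeros(X.shape[1])
            self.x_scale_ = np.ones(X.shape[1])
        Xs = (X - self.x_mean_) / self.x_scale_
        design = np.column_stack([np.ones(Xs.shape[0]), Xs])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = coef[0].copy()
        self.coef_ = coef[1:].T.copy()
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def b_(self) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return np.column_stack([self.intercept_, self.coef_])

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected (n_samples, {self.n_features_in_}) input")
        Xs = (X - self.x_mean_) / self.x_scale_
        return Xs @ self.coef_.T + self.intercept_


def _logistic(z: np.ndarray) -> np.ndarray:
    return expit(z)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ANNReconstructor(BaseEstimator, RegressorMixin):
    """Feedforward 3-6-12 network trained full-batch with L-BFGS.

    Hidden activation is the logistic sigmoid. Weights are initialized
    uniformly in +/- 1/sqrt(fan_in) from ``seed`` (biases at zero), so the
    fit is reproducible bit-for-bit for a fixed seed and dataset.

    Parameters
    ----------
    hidden_units : int, default 6
        Hidden layer width (6 in the reference design; exposed for sweeps).
    output_activation : {'linear', 'softmax'}, default 'linear'
    seed : int, default 0
    max_iter : int, default 300
        L-BFGS iteration cap; optimization stops earlier on a relative
        loss plateau (``tol``).
    tol : float, default 1e-10
        Relative reduction threshold (L-BFGS ``ftol``).
    scale_inputs : bool, default True
    """

    def __init__(
        self,
        hidden_units: int = 6,
        output_activation: str = "linear",
        seed: int = 0,
        max_iter: int = 300,
        tol: float = 1e-10,
        scale_inputs: bool = True,
    ):
        self.hidden_units = hidden_units
        self.output_activation = output_activation
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.scale_inputs = scale_inputs

    # -- parameter vector packing -------------------------------------------------
    def _shapes(self, n_in: int, n_out: int):
        h = self.hidden_units
        return [(n_in, h), (h,), (h, n_out), (n_out,)]

    @staticmethod
    def _unpack(theta: np.ndarray, shapes):
        out, i = [], 0
        for shp in shapes:
            size = int(np.prod(shp))
            out.append(theta[i : i + size].reshape(shp))
            i += size
        return out

    def _loss_grad(self, theta, X, Y, shapes):
        W1, b1, W2, b2 = self._unpack(theta, shapes)
        n, n_out = Y.shape
        H = _logistic(X @ W1 + b1)
        Z2 = H @ W2 + b2
        if self.output_activation == "softmax":
            P = _softmax(Z2)
            err = P - Y
            loss = 0.5 * np.mean(err**2)
            G = err / err.size
            dZ2 = P * (G - (G * P).sum(axis=1, keepdims=True))
        else:
            err = Z2 - Y
            loss = 0.5 * np.mean(err**2)
            dZ2 = err / err.size
        dW2 = H.T @ dZ2
        db2 = dZ2.sum(axis=0)
        dH = dZ2 @ W2.T
        dZ1 = dH * H * (1.0 - H)
        dW1 = X.T @ dZ1
        db1 = dZ1.sum(axis=0)
        grad = np.concatenate([a.ravel() for a in (dW1, db1, dW2, db2)])
        return loss, grad

    def fit(self, X, y):
        if self.output_activation not in ("linear", "softmax"):
            raise ValueError("output_activation must be 'linear' or 'softmax'")
        X, y = _validate_xy(X, y)
        if self.scale_inputs:
            self.x_mean_, self.x_scale_ = _fit_scaler(X)
        else:
            self.x_mean_ = np.zeros(X.shape[1])
            self.x_scale_ = np.ones(X.shape[1])
        self.y_mean_, self.y_scale_ = _fit_scaler(y, allow_constant=True)
        Xs = (X - self.x_mean_) / self.x_scale_
        Ys = (y - self.y_mean_) / self.y_scale_

        n_in, n_out = X.shape[1], y.shape[1]
        shapes = self._shapes(n_in, n_out)
        rng = np.random.default_rng(self.seed)
        init = []
        for shp in shapes:
            if len(shp) == 2:
                bound = 1.0 / np.sqrt(shp[0])
                init.append(rng.uniform(-bound, bound, size=shp).ravel())
            else:
                init.append(np.zeros(shp))
        theta0 = np.concatenate(init)

        history: list[float] = []
        last_loss = [np.inf]

        def fun(theta):
            loss, grad = self._loss_grad(theta, Xs, Ys, shapes)
            last_loss[0] = float(loss)
            return loss, grad

        def record(theta):
            # L-BFGS line search guarantees the accepted point was the most
            # recent objective evaluation, so this logs the epoch loss cheaply.
            history.append(last_loss[0])

        history.append(float(self._loss_grad(theta0, Xs, Ys, shapes)[0]))
        res = minimize(
            fun,
            theta0,
            method="L-BFGS-B",
            jac=True,
            callback=record,
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-8},
        )
        if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
            raise RuntimeError("ANN training diverged: non-finite loss or weights")
        self.W1_, self.b1_, self.W2_, self.b2_ = [
            a.copy() for a in self._unpack(res.x, shapes)
        ]
        self.loss_history_ = np.asarray(history)
        self.n_iter_ = int(res.nit)
        self.n_features_in_ = n_in
        return self

    def _forward_standardized(self, Xs: np.ndarray) -> np.ndarray:
        H = _logistic(Xs @ self.W1_ + self.b1_)
        Z2 = H @ self.W2_ + self.b2_
        return _softmax(Z2) if self.output_activation == "softmax" else Z2

    def predict(self, X):
        check_is_fitted(self, "W1_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected (n_samples, {self.n_features_in_}) input")
        Xs = (X - self.x_mean_) / self.x_scale_
        return self._forward_standardized(Xs) * self.y_scale_ + self.y_mean_


class EnsembleReconstructor(BaseEstimator, RegressorMixin):
    """Average of ANN members trained from distinct random initializations."""

    def __init__(
        self,
        seeds: Sequence[int] = DEFAULT_ENSEMBLE_SEEDS,
        hidden_units: int = 6,
        output_activation: str = "linear",
        max_iter: int = 300,
        tol: float = 1e-10,
        scale_inputs: bool = True,
        require_distinct_seeds: bool = True,
    ):
        self.seeds = seeds
        self.hidden_units = hidden_units
        self.output_activation = output_activation
        self.max_iter = max_iter
        self.tol = tol
        self.scale_inputs = scale_inputs
        self.require_distinct_seeds = require_distinct_seeds

    def fit(self, X, y):
        seeds = tuple(int(s) for s in self.seeds)
        if not seeds:
            raise ValueError("need at least one ensemble seed")
        if self.require_distinct_seeds and len(set(seeds)) != len(seeds):
            raise ValueError("ensemble seeds must be distinct")
        self.members_ = []
        for s in seeds:
            member = ANNReconstructor(
                hidden_units=self.hidden_units,
                output_activation=self.output_activation,
                seed=s,
                max_iter=self.max_iter,
                tol=self.tol,
                scale_inputs=self.scale_inputs,
            )
            self.members_.append(member.fit(X, y))
        self.n_features_in_ = self.members_[0].n_features_in_
        return self

    def predict(self, X):
        check_is_fitted(self, "members_")
        preds = np.stack([m.predict(X) for m in self.members_])
        return preds.mean(axis=0)


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimators (channel-major signatures).

def fit_mlr(cl: np.ndarray, leads: np.ndarray, **kwargs) -> MLRReconstructor:
    """Fit MLR from chest leads (3, T) to reference leads (12, T)."""
    return MLRReconstructor(**kwargs).fit(np.asarray(cl).T, np.asarray(leads).T)


def fit_ann(
    cl: np.ndarray, leads: np.ndarray, seed: int = 0, **kwargs
) -> ANNReconstructor:
    """Fit a single ANN from chest leads (3, T) to reference leads (12, T)."""
    return ANNReconstructor(seed=seed, **kwargs).fit(
        np.asarray(cl).T, np.asarray(leads).T
    )


def fit_ensemble(
    cl: np.ndarray,
    leads: np.ndarray,
    seeds: Sequence[int] = DEFAULT_ENSEMBLE_SEEDS,
    **kwargs,
) -> EnsembleReconstructor:
    """Fit the 5-seed ANN ensemble from (3, T) chest leads to (12, T) leads."""
    return EnsembleReconstructor(seeds=seeds, **kwargs).fit(
        np.asarray(cl).T, np.asarray(leads).T
    )


def predict(model, cl: np.ndarray) -> np.ndarray:
    """Reconstruct (12, T) leads in uV from (3, T) chest leads."""
    return np.asarray(model.predict(np.asarray(cl).T)).T


# ---------------------------------------------------------------------------
# JSON serialization (documented schema: type, params, weights, statistics).

def _arr(a) -> list:
    return np.asarray(a, dtype=float).tolist()


def model_to_json(model) -> str:
    """Serialize a fitted reconstructor to a JSON string."""
    if isinstance(model, MLRReconstructor):
        payload = {
            "type": "mlr",
            "params": model.get_params(),
            "coef": _arr(model.coef_),
            "intercept": _arr(model.intercept_),
            "x_mean": _arr(model.x_mean_),
            "x_scale": _arr(model.x_scale_),
        }
    elif isinstance(model, ANNReconstructor):
        payload = {
            "type": "ann",
            "params": model.get_params(),
            "W1": _arr(model.W1_),
            "b1": _arr(model.b1_),
            "W2": _arr(model.W2_),
            "b2": _arr(model.b2_),
            "x_mean": _arr(model.x_mean_),
            "x_scale": _arr(model.x_scale_),
            "y_mean": _arr(model.y_mean_),
            "y_scale": _arr(model.y_scale_),
        }
    elif isinstance(model, EnsembleReconstructor):
        payload = {
            "type": "ensemble",
            "params": {
                k: (list(v) if k == "seeds" else v)
                for k, v in model.get_params().items()
            },
            "members": [json.loads(model_to_json(m)) for m in model.members_],
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    return json.dumps(payload)


def _restore_ann(payload: dict) -> ANNReconstructor:
    m = ANNReconstructor(**payload["params"])
    for key in ("W1", "b1", "W2", "b2", "x_mean", "x_scale", "y_mean", "y_scale"):
        setattr(m, f"{key}_", np.asarray(payload[key], dtype=float))
    m.n_features_in_ = m.W1_.shape[0]
    return m


def model_from_json(text: str):
    """Rebuild a fitted reconstructor from :func:`model_to_json` output."""
    payload = json.loads(text)
    kind = payload.get("type")
    if kind == "mlr":
        m = MLRReconstructor(**payload["params"])
        m.coef_ = np.asarray(payload["coef"], dtype=float)
        m.intercept_ = np.asarray(payload["intercept"], dtype=float)
        m.x_mean_ = np.asarray(payload["x_mean"], dtype=float)
        m.x_scale_ = np.asarray(payload["x_scale"], dtype=float)
        m.n_features_in_ = m.coef_.shape[1]
        return m
    if kind == "ann":
        return _restore_ann(payload)
    if kind == "ensemble":
        params = dict(payload["params"])
        params["seeds"] = tuple(params["seeds"])
        m = EnsembleReconstructor(**params)
        m.members_ = [_restore_ann(p) for p in payload["members"]]
        m.n_features_in_ = m.members_[0].n_features_in_
        return m
    raise ValueError(f"unknown serialized model type {kind!r}")
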