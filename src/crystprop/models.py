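"""Classifiers relating a 20-predictor encoding to crystallization success.

Two models are provided, both as scikit-learn-compatible estimators:

* :class:`LogisticPropensityModel` — logistic regression with 21
  coefficients b0..b20,

      P(y = 1 | x) = 1 / (1 + exp(-(b0 + b1 x1 + ... + b20 x20)))

  (standard sign convention). The historical variant with a positive
  exponent, P = 1/(1 + exp(+eta)), is supported through
  ``sign_convention="paper"``: after refitting, the stored coefficients
  absorb the sign flip and predicted probabilities are identical.

* :class:`CrystallizationNet` — a 20 -> 10 -> 1 feed-forward network
  (tanh hidden layer, logistic output), trained full-batch with L-BFGS on
  cross-entropy, deterministic given its seed.

Classification thresholds probabilities at 0.5, with ties assigned to the
positive class.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_X_y, check_array


def classify(p: float, threshold: float = 0.5) -> int:
    """Binary decision from a probability; ties (p == threshold) go to 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return int(p >= threshold)


class LogisticPropensityModel(ClassifierMixin, BaseEstimator):
    """Logistic regression on the 20 amino-acid predictors.

    Parameters
    ----------
    alpha:
        L2 penalty strength (lambda >= 0); 0 gives plain maximum likelihood.
    sign_convention:
        ``"standard"`` stores b such that P = sigmoid(b0 + b.x);
        ``"paper"`` stores the negated coefficients so that
        P = 1/(1 + exp(b0 + b.x)). Predictions are identical either way.
    max_iter, tol:
        Optimiser budget and gradient tolerance.

    Attributes
    ----------
    b_ : ndarray of shape (21,)
        Intercept b0 followed by b1..b20, on the raw predictor scale, under
        the chosen sign convention.
    se_ : ndarray of shape (21,)
        Asymptotic standard errors from the observed Fisher information
        (NaN for coefficients pinned at 0 by a constant column).
    separation_fallback_ : bool
        True when complete separation forced an automatic refit with a
        small L2 penalty (1e-4).
    """

    _SEPARATION_ALPHA = 1e-4

    def __init__(self, alpha: float = 0.0, sign_convention: str = "standard",
                 max_iter: int = 500, tol: float = 1e-8):
        self.alpha = alpha
        self.sign_convention = sign_convention
        self.max_iter = max_iter
        self.tol = tol

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sign_convention not in ("standard", "paper"):
            raise ValueError(f"unknown sign convention {self.sign_convention!r}")
        X, y = check_X_y(X, y, ensure_min_samples=1)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        self.separation_fallback_ = False

        if len(np.unique(y)) == 1:
            # Degenerate: Bernoulli MLE is the prevalence; clip to keep the
            # intercept finite.
            p = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
            b = np.zeros(X.shape[1] + 1)
            b[0] = logit(p)
            self._store(b, np.full_like(b, np.nan))
            return self

        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        # relative tolerance: a numerically-constant column has sd at
        # rounding level of its magnitude
        active = sd > 1e-12 * np.maximum(1.0, np.abs(mu))
        if not active.all():
            warnings.warn(
                f"{int((~active).sum())} constant predictor column(s); "
                "their coefficients are fixed at 0", stacklevel=2
            )
        if not active.any():
            # no informative predictor: intercept-only model at prevalence
            p = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
            b = np.zeros(X.shape[1] + 1)
            b[0] = logit(p)
            self._store(b, np.full_like(b, np.nan))
            return self
        Z = (X[:, active] - mu[active]) / sd[active]

        bz = self._fit_standardized(Z, y, self.alpha)
        if self.alpha == 0 and np.abs(bz).max() > 30:
            warnings.warn(
                "complete separation detected; refitting with alpha=1e-4",
                stacklevel=2,
            )
            self.separation_fallback_ = True
            bz = self._fit_standardized(Z, y, self._SEPARATION_ALPHA)

        # map back to the raw predictor scale
        b = np.zeros(X.shape[1] + 1)
        coef_raw = bz[1:] / sd[active]
        b[1:][active] = coef_raw
        b[0] = bz[0] - coef_raw @ mu[active]

        se = np.full(X.shape[1] + 1, np.nan)
        se_active = self._standard_errors(X[:, active], y, b, active)
        se[0] = se_active[0]
        se[1:][active] = se_active[1:]
        self._store(b, se)
        return self

    def _fit_standardized(self, Z, y, alpha):
        lr = LogisticRegression(
            C=np.inf if alpha == 0 else 1.0 / alpha,
            solver="lbfgs", max_iter=self.max_iter, tol=self.tol,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*converge.*")
            lr.fit(Z, y)
        return np.concatenate([lr.intercept_, lr.coef_[0]])

    def _standard_errors(self, Xa, y, b, active):
        ones = np.ones((Xa.shape[0], 1))
        D = np.hstack([ones, Xa])
        eta = b[0] + Xa @ b[1:][active]
        p = expit(eta)
        w = p * (1 - p)
        info = D.T @ (D * w[:, None])
        if self.alpha > 0:
            info = info + self.alpha * np.eye(info.shape[0])
        try:
            cov = np.linalg.inv(info)
            return np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            return np.full(info.shape[0], np.nan)

    def _store(self, b_standard, se):
        # b_standard is always in the standard convention internally
        if self.sign_convention == "paper":
            self.b_ = -b_standard
        else:
            self.b_ = b_standard.copy()
        self.se_ = se
        self.coef_ = self._b_standard()[1:][None, :]
        self.intercept_ = self._b_standard()[:1]

    def _b_standard(self):
        return -self.b_ if self.sign_convention == "paper" else self.b_

    # -- prediction -------------------------------------------------------

    def decision_function(self, X):
        X = check_array(X)
        b = self._b_standard()
        return b[0] + X @ b[1:]

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X, threshold: float = 0.5):
        p = self.predict_proba(X)[:, 1]
        return (p >= threshold).astype(int)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "model": "logistic",
            "sign_convention": self.sign_convention,
            "alpha": self.alpha,
            "b": self.b_.tolist(),
            "se": np.where(np.isnan(self.se_), None, self.se_).tolist(),
            "separation_fallback": self.separation_fallback_,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LogisticPropensityModel":
        d = json.loads(text)
        model = cls(alpha=d["alpha"], sign_convention=d["sign_convention"])
        b = np.array(d["b"], dtype=float)
        model.n_features_in_ = len(b) - 1
        model.classes_ = np.array([0, 1])
        model.separation_fallback_ = d.get("separation_fallback", False)
        se = np.array([np.nan if v is None else v for v in d["se"]])
        model.b_ = b
        model.se_ = se
        model.coef_ = model._b_standard()[1:][None, :]
        model.intercept_ = model._b_standard()[:1]
        return model


class CrystallizationNet(ClassifierMixin, BaseEstimator):
    """Feed-forward 20 -> 10 -> 1 network (tanh hidden, logistic output).

    Trained full-batch with L-BFGS on the cross-entropy loss; bit-identical
    weights for identical (X, y, random_state). A single-class ``y`` is
    rejected — use the prevalence model instead.

    Attributes
    ----------
    W1_ : (hidden_units, n_features) hidden weights; b1_ : hidden biases.
    W2_ : (hidden_units,) output weights; b2_ : output bias (scalar).
    """

    def __init__(self, hidden_units: int = 10, random_state: int = 0,
                 max_iter: int = 500, tol: float = 1e-6, alpha: float = 1e-4):
        self.hidden_units = hidden_units
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.alpha = alpha

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError(
                "both classes must be present to train the network"
            )
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        # standardize for optimizer conditioning; fold back at predict time
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Z = (X - self._mu) / self._sd
        mlp = MLPClassifier(
            hidden_layer_sizes=(self.hidden_units,), activation="tanh",
            solver="lbfgs", alpha=self.alpha, max_iter=self.max_iter,
            tol=self.tol, random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*converge.*")
            mlp.fit(Z, y)
        self.W1_ = mlp.coefs_[0].T.copy()
        self.b1_ = mlp.intercepts_[0].copy()
        self.W2_ = mlp.coefs_[1].ravel().copy()
        self.b2_ = float(mlp.intercepts_[1][0])
        return self

    def predict_proba(self, X):
        X = check_array(X)
        Z = (X - self._mu) / self._sd
        h = np.tanh(Z @ self.W1_.T + self.b1_)
        p = expit(h @ self.W2_ + self.b2_)
        return np.column_stack([1 - p, p])

    def predict(self, X, threshold: float = 0.5):
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)

    def to_json(self) -> str:
        return json.dumps({
            "model": "nn",
            "hidden_units": self.hidden_units,
            "random_state": self.random_state,
            "W1": self.W1_.tolist(), "b1": self.b1_.tolist(),
            "W2": self.W2_.tolist(), "b2": self.b2_,
            "mu": self._mu.tolist(), "sd": self._sd.tolist(),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CrystallizationNet":
        d = json.loads(text)
        net = cls(hidden_units=d["hidden_units"], random_state=d["random_state"])
        net.W1_ = np.array(d["W1"])
        net.b1_ = np.array(d["b1"])
        net.W2_ = np.array(d["W2"])
        net.b2_ = float(d["b2"])
        net._mu = np.array(d["mu"])
        net._sd = np.array(d["sd"])
        net.n_features_in_ = net.W1_.shape[1]
        net.classes_ = np.array([0, 1])
        return net


# -- functional wrappers ---------------------------------------------------

def fit_logistic(X, y, alpha: float = 0.0, **kwargs) -> LogisticPropensityModel:
    """Fit a logistic model; thin wrapper over LogisticPropensityModel."""
    return LogisticPropensityModel(alpha=alpha, **kwargs).fit(X, y)


def predict_logistic(model: LogisticPropensityModel, x) -> float:
    """Predicted crystallization probability for a single 20-vector."""
    return float(model.predict_proba(np.asarray(x)[None, :])[0, 1])


def fit_nn(X, y, seed: int = 0, **config) -> CrystallizationNet:
    """Train the 20->10->1 network; thin wrapper over CrystallizationNet."""
    return CrystallizationNet(random_state=seed, **config).fit(X, y)


def save_model(model, path) -> None:
    Path(path).write_text(model.to_json())


def load_model(path):
    text = Path(path).read_text()
    kind = json.loads(text).get("model")
    if kind == "logistic":
        return LogisticPropensityModel.from_json(text)
    if kind == "nn":
        return CrystallizationNet.from_json(text)
    raise ValueError(f"{path}: unknown model kind {kind!r}")
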