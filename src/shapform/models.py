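"""Classifier contract: IRLS logistic regression plus library-backed ensembles.

The logistic path is implemented from scratch (penalized iteratively
reweighted least squares on standardized features) because its coefficients
feed the closed-form linear Shapley attribution downstream.  Tree ensembles
are adapters around scikit-learn behind the same fit/predict surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


class SingleClassError(ValueError):
    """Training labels contain only one class."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge (e.g. perfect separation with no penalty)."""


@dataclass
class FittedLinearModel:
    """Logistic model on standardized features, with scaling retained."""

    intercept: float
    coefficients: np.ndarray          # per standardized feature, log-odds
    feature_means: np.ndarray
    feature_scales: np.ndarray
    item_ids: list[str] | None = None
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_scales = np.asarray(self.feature_scales, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficients")
        if np.any(self.feature_scales <= 0):
            raise ValueError("feature scales must be positive")
        if self.item_ids is not None and len(self.item_ids) != self.coefficients.size:
            raise ValueError("item_ids do not align with coefficients")

    def _check_ids(self, item_ids) -> None:
        if item_ids is not None and self.item_ids is not None:
            if list(item_ids) != list(self.item_ids):
                raise ValueError("feature ids do not match the fitted model")

    def predict_margin(self, X, item_ids=None) -> np.ndarray:
        """Log-odds: intercept + sum beta * (x - mean) / scale."""
        self._check_ids(item_ids)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.feature_means) / self.feature_scales
        return self.intercept + Z @ self.coefficients

    def predict_proba(self, X, item_ids=None) -> np.ndarray:
        return expit(self.predict_margin(X, item_ids=item_ids))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)  # constant cols: leave centered
    return (X - means) / scales, means, scales


def fit_logistic(
    X,
    y,
    l2_penalty: float = 1.0,
    item_ids: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FittedLinearModel:
    """Penalized logistic regression by Newton/IRLS on standardized features.

    Maximizes ``loglik - l2_penalty/2 * ||beta||^2`` (intercept unpenalized);
    converged when the max absolute score component drops below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X and y are not aligned")
    if X.shape[0] < 2:
        raise ValueError("need at least two observations")
    classes = np.unique(y)
    if classes.size < 2:
        raise SingleClassError("y contains a single class; cannot fit")
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if l2_penalty < 0:
        raise ValueError("l2_penalty must be nonnegative")

    Z, means, scales = _standardize(X)
    n, p = Z.shape
    D = np.column_stack([np.ones(n), Z])
    beta = np.zeros(p + 1)
    beta[0] = np.log(y.mean() / (1 - y.mean()))  # warm start at base rate
    pen = np.r_[0.0, np.full(p, l2_penalty)]

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = D @ beta
        mu = expit(eta)
        score = D.T @ (y - mu) - pen * beta
        if np.max(np.abs(score)) < tol:
            break
        w = mu * (1 - mu)
        H = (D * w[:, None]).T @ D + np.diag(pen)
        # tiny ridge keeps the Newton step defined when w underflows
        H[np.diag_indices_from(H)] += 1e-12
        beta = beta + np.linalg.solve(H, score)
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e8:
            raise ConvergenceError(
                "diverging coefficients (likely perfect separation); "
                "set l2_penalty > 0"
            )
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations; "
            "consider increasing l2_penalty"
        )

    # unpenalized fits on separable data "converge" only because the score
    # underflows once fitted probabilities saturate; flag the runaway instead
    if l2_penalty == 0 and np.max(np.abs(beta)) > 30:
        raise ConvergenceError(
            "coefficients diverged (data likely perfectly separated); "
            "set l2_penalty > 0"
        )

    return FittedLinearModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        feature_means=means,
        feature_scales=scales,
        item_ids=list(item_ids) if item_ids is not None else None,
        n_iter=n_iter,
    )


def log_likelihood(model: FittedLinearModel, X, y) -> float:
    """Unpenalized Bernoulli log-likelihood of a fitted model."""
    eta = model.predict_margin(X)
    y = np.asarray(y, dtype=float).ravel()
    # log(sigma(eta)) = -log(1+exp(-eta)), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class SklearnAdapter:
    """Tree-ensemble (or any sklearn classifier) behind the same contract.

    Margins are logits of the predicted probability, clipped away from 0/1 so
    they remain finite.
    """

    estimator: object
    item_ids: list[str] | None = None
    _clip: float = field(default=1e-7, repr=False)

    def fit(self, X, y) -> "SklearnAdapter":
        y = np.asarray(y).ravel()
        if np.unique(y).size < 2:
            raise SingleClassError("y contains a single class; cannot fit")
        self.estimator.fit(np.asarray(X, dtype=float), y)
        return self

    def predict_proba(self, X, item_ids=None) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]
        return np.clip(proba, self._clip, 1 - self._clip)

    def predict_margin(self, X, item_ids=None) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.log(proba / (1 - proba))


def make_model(spec: dict | None):
    """Instantiate an unfitted model from a spec mapping.

    ``{"kind": "logistic", "l2_penalty": 1.0}`` is the implemented default;
    ``random_forest`` and ``gradient_boosting`` route to scikit-learn.
    """
    spec = dict(spec or {"kind": "logistic"})
    kind = spec.pop("kind", "logistic")
    if kind == "logistic":
        return _LogisticSpec(**spec)
    if kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return SklearnAdapter(RandomForestClassifier(**spec))
    if kind == "gradient_boosting":
        from sklearn.ensemble import GradientBoostingClassifier

        return SklearnAdapter(GradientBoostingClassifier(**spec))
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class _LogisticSpec:
    """Deferred logistic fit so make_model returns a uniform fit() surface."""

    l2_penalty: float = 1.0

    def fit(self, X, y, item_ids=None) -> FittedLinearModel:
        return fit_logistic(X, y, l2_penalty=self.l2_penalty, item_ids=item_ids)
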