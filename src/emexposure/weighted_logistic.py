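"""Maximum likelihood for Bernoulli regression with fractional record weights.

This is the numerical engine behind both EM sub-models: the outcome model is
fitted on a pseudo-record expansion in which each missing-exposure subject
appears twice with fractional weights, so the optimizer must stay stable
under tiny, non-integer weights. The solver is Newton with step-halving on
the weighted log-likelihood; convergence is declared on the gradient
sup-norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._utils import clip_prob, logistic

GRAD_TOL = 1e-8
MAX_HALVINGS = 25
#: |coefficient| beyond which the logistic is saturated: treated as separation.
SEPARATION_BOUND = 30.0


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix is collinear after dropping zero-weight rows."""


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE diverges."""


@dataclass(frozen=True)
class WeightedFitResult:
    """Converged weighted-logistic fit.

    ``covariance`` is the inverse negative Hessian of the weighted
    log-likelihood at the optimum.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_iter: int
    converged: bool


def bernoulli_loglik(
    y: np.ndarray,
    design: np.ndarray,
    coef: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted Bernoulli log-likelihood sum_i w_i [y_i log mu_i + (1-y_i) log(1-mu_i)].

    Probabilities are clipped 1e-12 from the boundary so the value is always
    finite.
    """
    y = np.asarray(y, dtype=float)
    design = np.asarray(design, dtype=float)
    coef = np.asarray(coef, dtype=float)
    if design.shape[0] != y.shape[0] or design.shape[1] != coef.shape[0]:
        raise ValueError(
            f"dimension mismatch: y {y.shape}, design {design.shape}, coef {coef.shape}"
        )
    if weights is None:
        weights = np.ones_like(y)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != y.shape:
            raise ValueError("weights misaligned with y")
    mu = clip_prob(logistic(design @ coef))
    return float(np.sum(weights * (y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu))))


def _check_rank(design: np.ndarray, names: list[str] | None) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = np.where(diag < 1e-10 * max(diag.max(), 1.0))[0]
        labels = [names[i] for i in bad] if names else list(bad)
        raise RankDeficiencyError(f"design is rank deficient; collinear columns: {labels}")


def fit_weighted_logistic(
    y: np.ndarray,
    design: np.ndarray,
    weights: np.ndarray | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    names: list[str] | None = None,
) -> WeightedFitResult:
    """Maximize the weighted Bernoulli log-likelihood by Newton's method.

    Each Newton step is halved (up to 25 times) until the log-likelihood
    does not decrease. Exit requires gradient sup-norm <= 1e-8. Raises on
    rank-deficient designs and on coefficient divergence past |coef| > 30
    (separation).
    """
    y = np.asarray(y, dtype=float)
    design = np.asarray(design, dtype=float)
    n, p = design.shape
    if weights is None:
        weights = np.ones(n)
    else:
        weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(weights > 0):
        raise ValueError("weights must not be all zero")

    active = weights > 0
    _check_rank(design[active], names)

    coef = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    ll = bernoulli_loglik(y, design, coef, weights)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        mu = logistic(design @ coef)
        grad = design.T @ (weights * (y - mu))
        if np.max(np.abs(grad)) <= GRAD_TOL:
            converged = True
            n_iter -= 1
            break
        w_irls = weights * mu * (1.0 - mu)
        hess = -(design.T * w_irls) @ design
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            # near-singular curvature from saturated probabilities
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        scale = 1.0
        for _ in range(MAX_HALVINGS + 1):
            trial = coef + scale * step
            ll_trial = bernoulli_loglik(y, design, trial, weights)
            if ll_trial >= ll - 1e-12:
                break
            scale *= 0.5
        coef = coef + scale * step
        ll = ll_trial
        if np.max(np.abs(coef)) > SEPARATION_BOUND:
            raise SeparationError(
                "coefficients diverged past |coef| > 30; "
                "data are (quasi-)separated for this design"
            )
    else:
        mu = logistic(design @ coef)
        grad = design.T @ (weights * (y - mu))
        converged = bool(np.max(np.abs(grad)) <= GRAD_TOL)

    mu = logistic(design @ coef)
    w_irls = weights * mu * (1.0 - mu)
    info = (design.T * w_irls) @ design
    covariance = np.linalg.inv(info)
    covariance = 0.5 * (covariance + covariance.T)
    return WeightedFitResult(
        coefficients=coef,
        covariance=covariance,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
    )


class WeightedLogisticRegression(BaseEstimator):
    """Bernoulli regression with per-record nonnegative weights.

    scikit-learn-style wrapper over :func:`fit_weighted_logistic`. The
    design matrix is taken as given (including any intercept column);
    no penalty is applied.

    Parameters
    ----------
    max_iter : int
        Newton iteration cap.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Maximum-likelihood coefficients.
    covariance_ : ndarray of shape (n_features, n_features)
        Inverse negative Hessian at the optimum.
    loglik_ : float
        Weighted log-likelihood at the optimum.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, max_iter: int = 100):
        self.max_iter = max_iter

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D and aligned with y")
        result = fit_weighted_logistic(y, X, weights=sample_weight, max_iter=self.max_iter)
        self.coef_ = result.coefficients
        self.covariance_ = result.covariance
        self.loglik_ = result.loglik
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        p1 = logistic(X @ self.coef_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
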