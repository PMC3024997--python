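"""EM maximum-likelihood estimation of an outcome-exposure association when
the binary exposure is missing for a large fraction of subjects.

The joint model factorizes as P(Y | X, W; beta) * P(X | Z; gamma): a logistic
outcome model in the exposure X and confounders W (optionally gender and a
gender-by-exposure product), and a logistic exposure model in the covariates
Z. For a subject with missing X the exposure prior is tilted by a sensitivity
ratio r in [0, 1]:

    P(X = 1 | Z, missing) = r * pi(Z),    pi(Z) = logistic(gamma . Z)

r = 1 recovers missing-at-random given (Z, Y); r < 1 encodes that untested
subjects are systematically less likely exposed (not missing at random). r is
fixed by the analyst — it cannot be estimated from the data — and is varied
in sensitivity sweeps.

The E-step gives each missing-X subject the posterior weight

    w_i = r pi_i f1_i / (r pi_i f1_i + (1 - r pi_i) f0_i)

where f1, f0 are the outcome Bernoulli likelihoods under X=1 and X=0. The
M-step refits the outcome model on a pseudo-record expansion (X=1 with
weight w_i, X=0 with weight 1-w_i) and maximizes the tilted exposure
objective Q(gamma) by Newton; at r = 1 the latter reduces exactly to a
weighted logistic fit on the same expansion. Each sweep of E and M steps
increases the observed-data log-likelihood, which is tracked per iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._utils import Z_95, clip_prob, logistic
from .cohort import NEGATIVE, POSITIVE, CohortTable, ModelSpec, encode_design
from .weighted_logistic import fit_weighted_logistic

logger = logging.getLogger(__name__)

GAMMA_GRAD_TOL = 1e-8


@dataclass(frozen=True)
class EMSettings:
    """Tuning knobs for one EM fit.

    ``r`` is the NMAR sensitivity ratio (1 = MAR). Convergence is declared
    when the parameter sup-norm change drops below ``tol``.
    """

    r: float = 1.0
    tol: float = 1e-6
    max_iter: int = 500
    variance_method: Literal["observed_hessian", "bootstrap", "none"] = "observed_hessian"
    bootstrap_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must be in [0, 1], got {self.r}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class EffectEstimate:
    """Odds ratio with Wald 95% CI and two-sided p-value for one term."""

    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low):  # NaN when the fit skipped variance estimation
            assert self.ci_low <= self.odds_ratio <= self.ci_high


@dataclass
class EMFit:
    """A converged (or flagged non-converged) EM fit.

    ``covariance`` is joint over (beta, gamma) in that order. ``weights``
    holds, for each missing-exposure record, the posterior probability that
    X = 1 at the optimum.
    """

    beta: np.ndarray
    beta_names: list[str]
    gamma: np.ndarray
    gamma_names: list[str]
    covariance: np.ndarray
    loglik_trajectory: np.ndarray
    weights: pd.Series
    n_iter: int
    converged: bool
    model_spec: ModelSpec
    settings: EMSettings

    @property
    def loglik(self) -> float:
        return float(self.loglik_trajectory[-1])

    def coef_table(self) -> pd.DataFrame:
        names = self.beta_names + self.gamma_names
        se = np.sqrt(np.diag(self.covariance))
        return pd.DataFrame(
            {
                "model": ["outcome"] * len(self.beta_names) + ["exposure"] * len(self.gamma_names),
                "term": names,
                "coef": np.concatenate([self.beta, self.gamma]),
                "se": se,
            }
        )


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _Prepared:
    """Arrays extracted once from a cohort table for a given model spec."""

    y: np.ndarray                 # outcome, all usable rows
    x: np.ndarray                 # exposure 0/1 with NaN for missing
    obs: np.ndarray               # bool mask: exposure observed
    z_design: np.ndarray          # exposure-model design (intercept first)
    z_names: list[str]
    w_base: np.ndarray            # outcome-model columns other than exposure
    w_names: list[str]            # names excluding intercept/exposure
    gender_male: np.ndarray | None  # only when a product term is present
    beta_names: list[str]
    index: pd.Index

    def outcome_design(self, x: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(x), x]
        if self.w_base.shape[1]:
            cols.append(self.w_base)
        if self.gender_male is not None:
            cols.append((self.gender_male * x)[:, None])
        return np.column_stack(cols) if len(cols) > 1 else np.ones((len(x), 1))


def _prepare(table: CohortTable, spec: ModelSpec) -> _Prepared:
    df = table.df
    schema = table.schema
    product = spec.interaction
    covariate_terms = [
        t for t in spec.outcome_terms if t not in (spec.exposure, product)
    ]
    # complete-case in all requested covariates (Z and W); exposure may be missing
    needed = list(dict.fromkeys(list(spec.exposure_terms) + covariate_terms))
    needed_cols = ["gender" if t == "gender" else t for t in needed]
    keep = df.index
    if needed_cols:
        keep = df.index[df[needed_cols].notna().all(axis=1)]
    dropped = len(df) - len(keep)
    if dropped:
        logger.info("excluding %d records with absent covariate values", dropped)
    sub = df.loc[keep]

    status = sub["hypoxia"].fillna("unknown") if "hypoxia" in sub.columns else pd.Series("unknown", index=keep)
    x = np.full(len(sub), np.nan)
    x[(status == POSITIVE).to_numpy()] = 1.0
    x[(status == NEGATIVE).to_numpy()] = 0.0
    obs = ~np.isnan(x)
    if obs.any():
        observed_levels = set(np.unique(x[obs]))
        if observed_levels != {0.0, 1.0}:
            raise ValueError(
                "exposure model unidentifiable: need observed records at both "
                f"exposure levels, saw {sorted(observed_levels)}"
            )
    else:
        raise ValueError("no records with observed exposure")

    z_design, z_names, z_keep = encode_design(sub, spec.exposure_terms, schema)
    assert len(z_keep) == len(sub)  # absent covariates were already excluded

    w_design, w_names, _ = encode_design(sub, covariate_terms, schema)
    w_base = w_design[:, 1:]  # drop the intercept; outcome_design adds its own
    w_names = w_names[1:]

    gender_male = None
    beta_names = ["intercept", spec.exposure] + list(w_names)
    if product is not None:
        if sub["gender"].nunique() < 2:
            raise ValueError("interaction model requires both genders present")
        if "gender=male" not in w_names:
            raise ValueError("product term requires 'gender' among outcome terms")
        gender_male = (sub["gender"] == "male").to_numpy(float)
        beta_names = beta_names + [f"gender=male:{spec.exposure}"]

    return _Prepared(
        y=sub["asd"].to_numpy(float),
        x=x,
        obs=obs,
        z_design=z_design,
        z_names=z_names,
        w_base=w_base,
        w_names=list(w_names),
        gender_male=gender_male,
        beta_names=beta_names,
        index=keep,
    )


# ---------------------------------------------------------------------------
# E step


def _e_step_arrays(
    data: _Prepared, beta: np.ndarray, gamma: np.ndarray, r: float
) -> np.ndarray:
    """Posterior P(X=1 | Y, Z, missing) for the missing-exposure rows."""
    miss = ~data.obs
    if not miss.any():
        return np.empty(0)
    y = data.y[miss]
    pi = logistic(data.z_design[miss] @ gamma)
    p1 = r * pi
    assert np.all(p1 <= 1.0 + 1e-12), "r*pi exceeded 1; r must be <= 1"
    sub = _Prepared(
        y=y,
        x=np.empty(0),
        obs=np.empty(0, bool),
        z_design=np.empty((0, 0)),
        z_names=[],
        w_base=data.w_base[miss],
        w_names=data.w_names,
        gender_male=None if data.gender_male is None else data.gender_male[miss],
        beta_names=data.beta_names,
        index=pd.Index([]),
    )
    mu1 = clip_prob(logistic(sub.outcome_design(np.ones_like(y)) @ beta))
    mu0 = clip_prob(logistic(sub.outcome_design(np.zeros_like(y)) @ beta))
    f1 = np.where(y == 1.0, mu1, 1.0 - mu1)
    f0 = np.where(y == 1.0, mu0, 1.0 - mu0)
    num = p1 * f1
    den = num + (1.0 - p1) * f0
    return num / np.maximum(den, 1e-300)


def e_step(
    table: CohortTable,
    model_spec: ModelSpec,
    beta: np.ndarray,
    gamma: np.ndarray,
    r: float,
) -> pd.Series:
    """Fractional weights for the missing-exposure records of ``table``.

    Observed records are untouched (they do not appear in the result).
    """
    data = _prepare(table, model_spec)
    w = _e_step_arrays(data, np.asarray(beta, float), np.asarray(gamma, float), r)
    return pd.Series(w, index=data.index[~data.obs], name="weight_x1")


# ---------------------------------------------------------------------------
# M step


def _expand_outcome(data: _Prepared, weights_miss: np.ndarray):
    """Pseudo-record expansion: observed rows once, missing rows twice."""
    miss = ~data.obs
    y_obs = data.y[data.obs]
    x_obs = data.x[data.obs]
    obs_part = _subset_prepared(data, data.obs).outcome_design(x_obs)
    if not miss.any():
        return y_obs, obs_part, np.ones_like(y_obs)
    miss_data = _subset_prepared(data, miss)
    y_miss = data.y[miss]
    d1 = miss_data.outcome_design(np.ones_like(y_miss))
    d0 = miss_data.outcome_design(np.zeros_like(y_miss))
    y_all = np.concatenate([y_obs, y_miss, y_miss])
    design = np.vstack([obs_part, d1, d0])
    w_all = np.concatenate([np.ones_like(y_obs), weights_miss, 1.0 - weights_miss])
    return y_all, design, w_all


def _subset_prepared(data: _Prepared, mask: np.ndarray) -> _Prepared:
    return _Prepared(
        y=data.y[mask],
        x=data.x[mask],
        obs=data.obs[mask],
        z_design=data.z_design[mask],
        z_names=data.z_names,
        w_base=data.w_base[mask],
        w_names=data.w_names,
        gender_male=None if data.gender_male is None else data.gender_male[mask],
        beta_names=data.beta_names,
        index=data.index[mask],
    )


def _q_gamma(
    gamma: np.ndarray, data: _Prepared, weights_miss: np.ndarray, r: float
) -> float:
    """Expected complete-data objective for gamma under the tilted prior."""
    obs, miss = data.obs, ~data.obs
    s = clip_prob(logistic(data.z_design @ gamma))
    q = float(
        np.sum(data.x[obs] * np.log(s[obs]) + (1.0 - data.x[obs]) * np.log(1.0 - s[obs]))
    )
    if miss.any():
        rs = clip_prob(r * s[miss])
        q += float(
            np.sum(weights_miss * np.log(rs) + (1.0 - weights_miss) * np.log(1.0 - rs))
        )
    return q


def _fit_gamma(
    data: _Prepared,
    weights_miss: np.ndarray,
    r: float,
    start: np.ndarray,
    max_iter: int = 100,
) -> np.ndarray:
    """Newton maximization of Q(gamma) with step-halving.

    At r = 1 the objective is exactly a weighted logistic log-likelihood on
    the pseudo-record expansion; for r < 1 the missing-record term is tilted
    and the Newton direction is safeguarded (gradient ascent fallback when
    the Hessian is not negative definite along the step).
    """
    obs, miss = data.obs, ~data.obs
    z = data.z_design
    gamma = start.copy()
    q = _q_gamma(gamma, data, weights_miss, r)
    for _ in range(max_iter):
        s = logistic(z @ gamma)
        grad = z[obs].T @ (data.x[obs] - s[obs])
        hess_diag = -(s[obs] * (1.0 - s[obs]))
        hess = (z[obs].T * hess_diag) @ z[obs]
        if miss.any():
            sm = s[miss]
            w = weights_miss
            one_m_rs = np.maximum(1.0 - r * sm, 1e-12)
            h = w * (1.0 - sm) - (1.0 - w) * r * sm * (1.0 - sm) / one_m_rs
            grad = grad + z[miss].T @ h
            hprime = -w - (1.0 - w) * r * (
                (1.0 - 2.0 * sm) * one_m_rs + r * sm * (1.0 - sm)
            ) / one_m_rs**2
            hess = hess + (z[miss].T * (hprime * sm * (1.0 - sm))) @ z[miss]
        if np.max(np.abs(grad)) <= GAMMA_GRAD_TOL:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = grad
        if step @ grad <= 0:  # not an ascent direction: fall back to gradient
            step = grad
        scale = 1.0
        for _ in range(26):
            trial = gamma + scale * step
            q_trial = _q_gamma(trial, data, weights_miss, r)
            if q_trial >= q - 1e-12:
                break
            scale *= 0.5
        gamma = gamma + scale * step
        q = q_trial
    return gamma


def m_step(
    table: CohortTable,
    model_spec: ModelSpec,
    weights: pd.Series,
    r: float,
    beta_start: np.ndarray | None = None,
    gamma_start: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One maximization step given E-step weights: returns (beta, gamma)."""
    data = _prepare(table, model_spec)
    w_miss = weights.reindex(data.index[~data.obs]).to_numpy(float)
    y_all, design, w_all = _expand_outcome(data, w_miss)
    beta = fit_weighted_logistic(
        y_all, design, w_all, start=beta_start, names=data.beta_names
    ).coefficients
    gamma0 = np.zeros(data.z_design.shape[1]) if gamma_start is None else np.asarray(gamma_start, float)
    gamma = _fit_gamma(data, w_miss, r, gamma0)
    return beta, gamma


# ---------------------------------------------------------------------------
# observed-data likelihood


def _observed_loglik_arrays(
    data: _Prepared, beta: np.ndarray, gamma: np.ndarray, r: float
) -> float:
    obs, miss = data.obs, ~data.obs
    pi = clip_prob(logistic(data.z_design @ gamma))
    ll = 0.0
    if obs.any():
        d = _subset_prepared(data, obs)
        mu = clip_prob(logistic(d.outcome_design(data.x[obs]) @ beta))
        y = data.y[obs]
        ll += float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))
        x = data.x[obs]
        ll += float(np.sum(x * np.log(pi[obs]) + (1.0 - x) * np.log(1.0 - pi[obs])))
    if miss.any():
        d = _subset_prepared(data, miss)
        y = data.y[miss]
        mu1 = clip_prob(logistic(d.outcome_design(np.ones_like(y)) @ beta))
        mu0 = clip_prob(logistic(d.outcome_design(np.zeros_like(y)) @ beta))
        f1 = np.where(y == 1.0, mu1, 1.0 - mu1)
        f0 = np.where(y == 1.0, mu0, 1.0 - mu0)
        p1 = r * pi[miss]
        ll += float(np.sum(np.log(np.maximum(p1 * f1 + (1.0 - p1) * f0, 1e-300))))
    return ll


def observed_loglik(
    table: CohortTable,
    model_spec: ModelSpec,
    beta: np.ndarray,
    gamma: np.ndarray,
    r: float,
) -> float:
    """The observed-data log-likelihood with missing X summed out.

    Observed rows contribute both model terms; missing rows contribute the
    two-component mixture log[f(Y|1,W) r pi + f(Y|0,W)(1 - r pi)].
    """
    data = _prepare(table, model_spec)
    return _observed_loglik_arrays(
        data, np.asarray(beta, float), np.asarray(gamma, float), r
    )


# ---------------------------------------------------------------------------
# full EM


def _run_em(data: _Prepared, settings: EMSettings):
    r = settings.r
    # complete-case initialization
    obs_data = _subset_prepared(data, data.obs)
    x_obs = data.x[data.obs]
    beta = fit_weighted_logistic(
        data.y[data.obs],
        obs_data.outcome_design(x_obs),
        names=data.beta_names,
    ).coefficients
    gamma = fit_weighted_logistic(
        x_obs, obs_data.z_design, names=data.z_names
    ).coefficients

    trajectory = [_observed_loglik_arrays(data, beta, gamma, r)]
    miss = ~data.obs
    w = np.empty(0)
    converged = False
    n_iter = 0
    for n_iter in range(1, settings.max_iter + 1):
        w = _e_step_arrays(data, beta, gamma, r)
        y_all, design, w_all = _expand_outcome(data, w)
        beta_new = fit_weighted_logistic(
            y_all, design, w_all, start=beta, names=data.beta_names
        ).coefficients
        gamma_new = _fit_gamma(data, w, r, gamma)
        trajectory.append(_observed_loglik_arrays(data, beta_new, gamma_new, r))
        delta = max(
            np.max(np.abs(beta_new - beta)), np.max(np.abs(gamma_new - gamma))
        )
        beta, gamma = beta_new, gamma_new
        if delta < settings.tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge within %d iterations", settings.max_iter)
    w = _e_step_arrays(data, beta, gamma, r)
    return beta, gamma, np.asarray(trajectory), w, n_iter, converged


def _numeric_hessian(fun, theta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with per-coordinate steps 1e-4 * (1 + |t|)."""
    p = len(theta)
    h = 1e-4 * (1.0 + np.abs(theta))
    hess = np.empty((p, p))
    f0 = fun(theta)
    for j in range(p):
        ej = np.zeros(p)
        ej[j] = h[j]
        hess[j, j] = (fun(theta + ej) + fun(theta - ej) - 2.0 * f0) / h[j] ** 2
    for j in range(p):
        for k in range(j + 1, p):
            ej = np.zeros(p)
            ek = np.zeros(p)
            ej[j] = h[j]
            ek[k] = h[k]
            val = (
                fun(theta + ej + ek)
                - fun(theta + ej - ek)
                - fun(theta - ej + ek)
                + fun(theta - ej - ek)
            ) / (4.0 * h[j] * h[k])
            hess[j, k] = hess[k, j] = val
    return hess


def fit_em(
    table: CohortTable,
    model_spec: ModelSpec,
    settings: EMSettings | None = None,
) -> EMFit:
    """Fit both models by EM and estimate the joint covariance.

    Initialization is by complete-case fits on the observed-exposure
    records. Iterations alternate the E step (posterior exposure weights
    under the tilted prior r*pi) and the M step (weighted refits) until the
    parameter sup-norm change falls below ``settings.tol``. The
    observed-data log-likelihood is recorded every iteration; it is
    nondecreasing for any fixed r. A fit that exhausts ``max_iter`` is
    returned with ``converged=False``, never silently.
    """
    settings = settings or EMSettings()
    data = _prepare(table, model_spec)
    beta, gamma, trajectory, w, n_iter, converged = _run_em(data, settings)

    covariance = _covariance(data, beta, gamma, table, model_spec, settings)
    return EMFit(
        beta=beta,
        beta_names=data.beta_names,
        gamma=gamma,
        gamma_names=data.z_names,
        covariance=covariance,
        loglik_trajectory=trajectory,
        weights=pd.Series(w, index=data.index[~data.obs], name="weight_x1"),
        n_iter=n_iter,
        converged=converged,
        model_spec=model_spec,
        settings=settings,
    )


def _covariance(
    data: _Prepared,
    beta: np.ndarray,
    gamma: np.ndarray,
    table: CohortTable,
    model_spec: ModelSpec,
    settings: EMSettings,
) -> np.ndarray:
    if settings.variance_method == "observed_hessian":
        p_beta = len(beta)
        theta = np.concatenate([beta, gamma])

        def fun(t: np.ndarray) -> float:
            return _observed_loglik_arrays(data, t[:p_beta], t[p_beta:], settings.r)

        hess = _numeric_hessian(fun, theta)
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "observed-information matrix is singular; try variance_method='bootstrap'"
            ) from exc
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError(
                "observed-information covariance has nonpositive diagonal; "
                "try variance_method='bootstrap'"
            )
        return 0.5 * (cov + cov.T)
    if settings.variance_method == "bootstrap":
        return _bootstrap_covariance(table, model_spec, settings)
    if settings.variance_method == "none":
        p = len(beta) + len(gamma)
        return np.full((p, p), np.nan)
    raise ValueError(f"unknown variance method {settings.variance_method!r}")


def _bootstrap_covariance(
    table: CohortTable, model_spec: ModelSpec, settings: EMSettings
) -> np.ndarray:
    if settings.bootstrap_reps < 2:
        raise ValueError("bootstrap needs at least 2 replicates")
    rng = np.random.default_rng(settings.seed)
    draws = []
    df = table.df
    for _ in range(settings.bootstrap_reps):
        idx = rng.integers(0, len(df), size=len(df))
        boot = df.iloc[idx].reset_index(drop=True)
        boot = boot.assign(id=[f"b{i}" for i in range(len(boot))])
        boot_table = CohortTable(df=boot, schema=table.schema)
        data = _prepare(boot_table, model_spec)
        beta, gamma, *_ = _run_em(data, settings)
        draws.append(np.concatenate([beta, gamma]))
    return np.cov(np.asarray(draws), rowvar=False)


def variance(fit: EMFit, table: CohortTable, settings: EMSettings | None = None) -> np.ndarray:
    """Recompute the joint covariance of a converged fit.

    ``observed_hessian`` differentiates the observed-data log-likelihood at
    the optimum by central differences; ``bootstrap`` refits on resampled
    cohorts with a fixed seed.
    """
    settings = settings or fit.settings
    data = _prepare(table, fit.model_spec)
    return _covariance(data, fit.beta, fit.gamma, table, fit.model_spec, settings)


# ---------------------------------------------------------------------------
# complete-case comparator


@dataclass(frozen=True)
class CompleteCaseFit:
    """Outcome model fitted on observed-exposure records only."""

    coefficients: np.ndarray
    names: list[str]
    covariance: np.ndarray


def complete_case_fit(table: CohortTable, model_spec: ModelSpec) -> CompleteCaseFit:
    """Fit the outcome model discarding all missing-exposure subjects.

    The standard comparator for the EM estimator: unbiased only when
    missingness is noninformative, and inefficient regardless.
    """
    data = _prepare(table, model_spec)
    obs = _subset_prepared(data, data.obs)
    result = fit_weighted_logistic(
        data.y[data.obs],
        obs.outcome_design(data.x[data.obs]),
        names=data.beta_names,
    )
    return CompleteCaseFit(
        coefficients=result.coefficients,
        names=list(data.beta_names),
        covariance=result.covariance,
    )


# ---------------------------------------------------------------------------
# reporting


def effect_estimate(fit: EMFit, term: str) -> EffectEstimate:
    """Odds ratio, 95% Wald CI and two-sided p-value for an outcome term."""
    if term not in fit.beta_names:
        raise KeyError(f"term {term!r} not in outcome model: {fit.beta_names}")
    i = fit.beta_names.index(term)
    coef = float(fit.beta[i])
    se = float(np.sqrt(fit.covariance[i, i]))
    if np.isnan(se):  # fit ran with variance_method="none"
        return EffectEstimate(
            term=term,
            odds_ratio=float(np.exp(coef)),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=float("nan"),
        )
    z = coef / se if se > 0 else np.inf * np.sign(coef) if coef else 0.0
    p = 1.0 if (se == 0 and coef == 0) else 2.0 * stats.norm.sf(abs(z))
    return EffectEstimate(
        term=term,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - Z_95 * se)),
        ci_high=float(np.exp(coef + Z_95 * se)),
        p_value=float(min(p, 1.0)),
    )


def interaction_fit(
    table: CohortTable,
    model_spec: ModelSpec,
    settings: EMSettings | None = None,
) -> tuple[EffectEstimate, EMFit]:
    """Fit the outcome model with a gender-by-exposure product term.

    Returns the Wald test of the product coefficient (the ratio of the
    male to female exposure odds ratios) together with the full fit.
    """
    spec = model_spec.with_interaction()
    if table.df["gender"].nunique() < 2:
        raise ValueError("interaction test requires both genders in the table")
    fit = fit_em(table, spec, settings)
    return effect_estimate(fit, f"gender=male:{spec.exposure}"), fit


# ---------------------------------------------------------------------------
# sklearn-style front end


class EMExposureLogit(BaseEstimator):
    """EM estimator for a logistic outcome model with a partly missing
    binary exposure.

    Parameters mirror :class:`ModelSpec` and :class:`EMSettings`. ``fit``
    takes a :class:`~emexposure.cohort.CohortTable`; the fitted attributes
    expose both coefficient vectors, the joint covariance, the per-record
    posterior exposure weights and the log-likelihood trajectory.

    Examples
    --------
    >>> est = EMExposureLogit(exposure_terms=("maternal_age",), r=1.0)
    >>> est.fit(cohort)                          # doctest: +SKIP
    >>> est.effect("hypoxia")                    # doctest: +SKIP
    EffectEstimate(term='hypoxia', odds_ratio=..., ...)
    """

    def __init__(
        self,
        exposure: str = "hypoxia",
        outcome_terms: tuple[str, ...] = ("hypoxia",),
        exposure_terms: tuple[str, ...] = (),
        r: float = 1.0,
        tol: float = 1e-6,
        max_iter: int = 500,
        variance_method: str = "observed_hessian",
        bootstrap_reps: int = 200,
        random_state: int = 0,
    ):
        self.exposure = exposure
        self.outcome_terms = outcome_terms
        self.exposure_terms = exposure_terms
        self.r = r
        self.tol = tol
        self.max_iter = max_iter
        self.variance_method = variance_method
        self.bootstrap_reps = bootstrap_reps
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            exposure=self.exposure,
            outcome_terms=tuple(self.outcome_terms),
            exposure_terms=tuple(self.exposure_terms),
        )

    def _settings(self) -> EMSettings:
        return EMSettings(
            r=self.r,
            tol=self.tol,
            max_iter=self.max_iter,
            variance_method=self.variance_method,  # type: ignore[arg-type]
            bootstrap_reps=self.bootstrap_reps,
            seed=self.random_state,
        )

    def fit(self, X: CohortTable, y=None) -> "EMExposureLogit":
        result = fit_em(X, self._spec(), self._settings())
        self.fit_ = result
        self.beta_ = result.beta
        self.gamma_ = result.gamma
        self.coef_names_ = result.beta_names + result.gamma_names
        self.covariance_ = result.covariance
        self.weights_ = result.weights
        self.loglik_trajectory_ = result.loglik_trajectory
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        return self

    def effect(self, term: str | None = None) -> EffectEstimate:
        return effect_estimate(self.fit_, term or self.exposure)

    def predict_proba(self, X: CohortTable) -> np.ndarray:
        """P(Y=1) per record: exposure taken as observed, or averaged over
        the tilted prior r*pi(Z) where missing."""
        data = _prepare(X, self._spec())
        pi = logistic(data.z_design @ self.gamma_)
        mu1 = logistic(data.outcome_design(np.ones(len(data.y))) @ self.beta_)
        mu0 = logistic(data.outcome_design(np.zeros(len(data.y))) @ self.beta_)
        p1 = np.where(data.obs, data.x, self.r * pi)
        p = p1 * mu1 + (1.0 - p1) * mu0
        return np.column_stack([1.0 - p, p])
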