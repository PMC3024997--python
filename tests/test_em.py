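import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize
from sklearn.base import clone

from emexposure import (
    CohortSchema,
    CohortTable,
    EMExposureLogit,
    EMSettings,
    ModelSpec,
    complete_case_fit,
    e_step,
    effect_estimate,
    fit_em,
    fit_weighted_logistic,
    interaction_fit,
    m_step,
    observed_loglik,
    simulate_cohort,
    variance,
)
from emexposure.em import EMFit, _fit_gamma, _prepare, _q_gamma

from conftest import dense_config


def _logit(p):
    return float(np.log(p / (1 - p)))


def _sim(n=400, seed=0, **kw):
    config = dense_config(n=n, seed=seed, **kw)
    return simulate_cohort(config, seed=seed), config


def _no_z_table(records):
    """Tiny cohort without Z covariates (exposure model is intercept-only)."""
    df = pd.DataFrame(records)
    df["id"] = [f"t{i}" for i in range(len(df))]
    if "gender" not in df:
        df["gender"] = "male"
    return CohortTable(df=df, schema=CohortSchema(covariates={}))


# ---------------------------------------------------------------------------
# E step


def test_e_step_zero_r_gives_zero_weights():
    table = _no_z_table(
        [
            {"asd": 1, "hypoxia": None},
            {"asd": 0, "hypoxia": None},
            {"asd": 0, "hypoxia": "positive"},
            {"asd": 1, "hypoxia": "negative"},
        ]
    )
    spec = ModelSpec(outcome_terms=("hypoxia",), exposure_terms=())
    w = e_step(table, spec, beta=np.array([-1.0, 0.5]), gamma=np.array([0.0]), r=0.0)
    assert len(w) == 2
    assert (w == 0.0).all()


def test_e_step_null_exposure_effect_gives_prior_weights():
    """When the outcome model carries no exposure effect, the posterior
    equals the tilted prior r*pi."""
    table = _no_z_table(
        [{"asd": y, "hypoxia": None} for y in (0, 1, 0)]
        + [{"asd": 0, "hypoxia": "positive"}, {"asd": 1, "hypoxia": "negative"}]
    )
    spec = ModelSpec(outcome_terms=("hypoxia",), exposure_terms=())
    pi = 0.3
    r = 0.6
    w = e_step(table, spec, beta=np.array([-2.0, 0.0]), gamma=np.array([_logit(pi)]), r=r)
    np.testing.assert_allclose(w.to_numpy(), r * pi, atol=1e-12)


def test_e_step_matches_hand_bayes_formula():
    """One missing case: weight checked against a hand evaluation of
    p1*f1 / (p1*f1 + (1-p1)*f0)."""
    pi, r = 0.2, 0.5
    b0, bx = _logit(0.01), np.log(2.0)
    table = _no_z_table(
        [
            {"asd": 1, "hypoxia": None},
            {"asd": 0, "hypoxia": "positive"},
            {"asd": 1, "hypoxia": "negative"},
        ]
    )
    spec = ModelSpec(outcome_terms=("hypoxia",), exposure_terms=())
    w = e_step(table, spec, beta=np.array([b0, bx]), gamma=np.array([_logit(pi)]), r=r)
    p1 = r * pi
    f1 = 1 / (1 + np.exp(-(b0 + bx)))  # P(Y=1 | X=1)
    f0 = 1 / (1 + np.exp(-b0))  # P(Y=1 | X=0)
    expected = p1 * f1 / (p1 * f1 + (1 - p1) * f0)
    assert w.iloc[0] == pytest.approx(expected, abs=1e-12)


def test_e_step_weights_in_unit_interval():
    table, config = _sim(n=300, seed=3)
    spec = config.model_spec()
    w = e_step(table, spec, beta=np.array([-1.0, 0.7, 1.0]), gamma=np.zeros(6), r=0.8)
    assert ((w >= 0) & (w <= 1)).all()


# ---------------------------------------------------------------------------
# M step


def test_m_step_no_missing_equals_independent_fits():
    table, config = _sim(n=500, seed=1)
    df = table.df.copy()
    df["hypoxia"] = np.where(df["truth_x"] == 1, "positive", "negative")
    full = CohortTable(df=df, schema=table.schema)
    spec = config.model_spec()
    beta, gamma = m_step(full, spec, weights=pd.Series(dtype=float), r=1.0)

    data = _prepare(full, spec)
    beta_direct = fit_weighted_logistic(data.y, data.outcome_design(data.x)).coefficients
    gamma_direct = fit_weighted_logistic(data.x, data.z_design).coefficients
    np.testing.assert_allclose(beta, beta_direct, atol=1e-9)
    np.testing.assert_allclose(gamma, gamma_direct, atol=1e-9)


def test_m_step_gamma_r1_reduces_to_weighted_logistic():
    """At r=1 the tilted Newton objective equals a weighted logistic fit on
    the two-pseudo-record expansion."""
    table, config = _sim(n=400, seed=2)
    spec = config.model_spec()
    data = _prepare(table, spec)
    rng = np.random.default_rng(0)
    w_miss = rng.uniform(0.05, 0.95, size=int((~data.obs).sum()))
    gamma_newton = _fit_gamma(data, w_miss, r=1.0, start=np.zeros(data.z_design.shape[1]))

    z_obs = data.z_design[data.obs]
    z_miss = data.z_design[~data.obs]
    y_exp = np.concatenate([data.x[data.obs], np.ones(len(w_miss)), np.zeros(len(w_miss))])
    z_exp = np.vstack([z_obs, z_miss, z_miss])
    w_exp = np.concatenate([np.ones(int(data.obs.sum())), w_miss, 1 - w_miss])
    gamma_wls = fit_weighted_logistic(y_exp, z_exp, w_exp).coefficients
    np.testing.assert_allclose(gamma_newton, gamma_wls, atol=1e-8)


def test_m_step_gamma_matches_derivative_free_optimizer():
    table, config = _sim(n=200, seed=4)
    spec = config.model_spec()
    data = _prepare(table, spec)
    rng = np.random.default_rng(1)
    w_miss = rng.uniform(0.1, 0.6, size=int((~data.obs).sum()))
    r = 0.5
    gamma_newton = _fit_gamma(data, w_miss, r=r, start=np.zeros(data.z_design.shape[1]))
    res = optimize.minimize(
        lambda g: -_q_gamma(g, data, w_miss, r),
        np.zeros(data.z_design.shape[1]),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    np.testing.assert_allclose(gamma_newton, res.x, atol=1e-5)
    assert _q_gamma(gamma_newton, data, w_miss, r) >= res.fun * -1 - 1e-10


# ---------------------------------------------------------------------------
# observed-data log-likelihood


def test_observed_loglik_no_missing_is_sum_of_model_logliks():
    table, config = _sim(n=300, seed=5)
    df = table.df.copy()
    df["hypoxia"] = np.where(df["truth_x"] == 1, "positive", "negative")
    full = CohortTable(df=df, schema=table.schema)
    spec = config.model_spec()
    data = _prepare(full, spec)
    beta = np.array([-1.2, 0.4, 0.9])
    gamma = np.array([-1.5, 0.2, 0.3, 0.6, -0.2, 0.4])
    ll = observed_loglik(full, spec, beta, gamma, r=1.0)
    from emexposure import bernoulli_loglik

    expected = bernoulli_loglik(data.y, data.outcome_design(data.x), beta) + bernoulli_loglik(
        data.x, data.z_design, gamma
    )
    assert ll == pytest.approx(expected, abs=1e-9)


def test_observed_loglik_single_missing_record_hand_sum():
    pi, r = 0.25, 0.7
    b0, bx = _logit(0.05), np.log(3.0)
    table = _no_z_table(
        [
            {"asd": 1, "hypoxia": None},
            {"asd": 0, "hypoxia": "positive"},
            {"asd": 0, "hypoxia": "negative"},
        ]
    )
    spec = ModelSpec(outcome_terms=("hypoxia",), exposure_terms=())
    beta = np.array([b0, bx])
    gamma = np.array([_logit(pi)])
    ll = observed_loglik(table, spec, beta, gamma, r)
    mu1 = 1 / (1 + np.exp(-(b0 + bx)))
    mu0 = 1 / (1 + np.exp(-b0))
    miss_term = np.log(r * pi * mu1 + (1 - r * pi) * mu0)  # Y=1, X unknown
    obs_terms = (
        np.log(1 - mu1) + np.log(pi)  # observed positive, Y=0
        + np.log(1 - mu0) + np.log(1 - pi)  # observed negative, Y=0
    )
    assert ll == pytest.approx(miss_term + obs_terms, abs=1e-10)


def test_observed_loglik_degenerate_prior_invariant_to_r():
    """A record whose exposure probability is ~0 contributes the same
    mixture term for every r."""
    table = _no_z_table(
        [
            {"asd": 1, "hypoxia": None},
            {"asd": 0, "hypoxia": "positive"},
            {"asd": 0, "hypoxia": "negative"},
        ]
    )
    spec = ModelSpec(outcome_terms=("hypoxia",), exposure_terms=())
    beta = np.array([-2.0, 1.0])
    gamma = np.array([-40.0])  # pi ~ 0
    values = [observed_loglik(table, spec, beta, gamma, r) for r in (0.1, 0.5, 1.0)]
    assert max(values) - min(values) < 1e-9


# ---------------------------------------------------------------------------
# full EM


def test_fit_em_zero_missing_is_fixed_point():
    table, config = _sim(n=500, seed=6)
    df = table.df.copy()
    df["hypoxia"] = np.where(df["truth_x"] == 1, "positive", "negative")
    full = CohortTable(df=df, schema=table.schema)
    spec = config.model_spec()
    fit = fit_em(full, spec, EMSettings(variance_method="none"))
    assert fit.converged and fit.n_iter == 1
    assert len(fit.weights) == 0

    data = _prepare(full, spec)
    beta_direct = fit_weighted_logistic(data.y, data.outcome_design(data.x)).coefficients
    gamma_direct = fit_weighted_logistic(data.x, data.z_design).coefficients
    np.testing.assert_allclose(fit.beta, beta_direct, atol=1e-8)
    np.testing.assert_allclose(fit.gamma, gamma_direct, atol=1e-8)


@pytest.mark.parametrize("r", [0.1, 0.5, 1.0])
def test_fit_em_matches_direct_maximization(r):
    """EM optimum equals a quasi-Newton maximization of the observed-data
    log-likelihood on a 200-record instance."""
    table, config = _sim(n=200, seed=7)
    spec = config.model_spec()
    fit = fit_em(table, spec, EMSettings(r=r, tol=1e-9, variance_method="none"))
    data = _prepare(table, spec)
    p_beta = len(fit.beta)

    def neg(theta):
        return -observed_loglik(table, spec, theta[:p_beta], theta[p_beta:], r)

    cc = complete_case_fit(table, spec)
    g0 = fit_weighted_logistic(data.x[data.obs], data.z_design[data.obs]).coefficients
    res = optimize.minimize(
        neg, np.concatenate([cc.coefficients, g0]), method="BFGS",
        options={"gtol": 1e-10, "maxiter": 5000},
    )
    np.testing.assert_allclose(np.concatenate([fit.beta, fit.gamma]), res.x, atol=1e-4)


def test_fit_em_trajectory_nondecreasing_and_weights_valid():
    for r in (0.2, 0.7, 1.0):
        table, config = _sim(n=400, seed=8)
        fit = fit_em(table, config.model_spec(), EMSettings(r=r, variance_method="none"))
        traj = fit.loglik_trajectory
        drops = np.diff(traj) / np.maximum(np.abs(traj[:-1]), 1.0)
        assert drops.min() >= -1e-8
        assert ((fit.weights >= 0) & (fit.weights <= 1)).all()
        assert fit.converged


def test_fit_em_nonconvergence_is_flagged():
    table, config = _sim(n=400, seed=9)
    fit = fit_em(table, config.model_spec(), EMSettings(max_iter=1, variance_method="none"))
    assert not fit.converged
    assert fit.n_iter == 1


def test_fit_em_unidentifiable_exposure_raises():
    table = _no_z_table(
        [{"asd": 0, "hypoxia": "positive"}, {"asd": 1, "hypoxia": None}]
    )
    spec = ModelSpec(outcome_terms=("hypoxia",), exposure_terms=())
    with pytest.raises(ValueError, match="unidentifiable|observed"):
        fit_em(table, spec, EMSettings(variance_method="none"))


# ---------------------------------------------------------------------------
# variance


def test_complete_data_covariance_matches_statsmodels():
    table, config = _sim(n=800, seed=10)
    df = table.df.copy()
    df["hypoxia"] = np.where(df["truth_x"] == 1, "positive", "negative")
    full = CohortTable(df=df, schema=table.schema)
    spec = config.model_spec()
    fit = fit_em(full, spec, EMSettings(variance_method="observed_hessian"))

    data = _prepare(full, spec)
    sm_out = sm.GLM(data.y, data.outcome_design(data.x), family=sm.families.Binomial()).fit()
    sm_exp = sm.GLM(data.x, data.z_design, family=sm.families.Binomial()).fit()
    p_beta = len(fit.beta)
    np.testing.assert_allclose(fit.covariance[:p_beta, :p_beta], sm_out.cov_params(), atol=1e-4)
    np.testing.assert_allclose(fit.covariance[p_beta:, p_beta:], sm_exp.cov_params(), atol=1e-4)
    # with no missing exposure the two blocks are orthogonal
    np.testing.assert_allclose(fit.covariance[:p_beta, p_beta:], 0.0, atol=1e-4)


def test_bootstrap_variance_requires_two_reps():
    table, config = _sim(n=300, seed=11)
    with pytest.raises(ValueError, match="2"):
        fit_em(
            table,
            config.model_spec(),
            EMSettings(variance_method="bootstrap", bootstrap_reps=1),
        )


def test_bootstrap_variance_close_to_hessian():
    table, config = _sim(n=600, seed=12)
    spec = config.model_spec()
    fit_h = fit_em(table, spec, EMSettings(variance_method="observed_hessian"))
    fit_b = fit_em(
        table, spec, EMSettings(variance_method="bootstrap", bootstrap_reps=60, seed=1)
    )
    se_h = np.sqrt(np.diag(fit_h.covariance))[1]
    se_b = np.sqrt(np.diag(fit_b.covariance))[1]
    assert se_b == pytest.approx(se_h, rel=0.5)  # same order, modest reps


# ---------------------------------------------------------------------------
# effect estimates


def _fake_fit(coef, se, term="hypoxia"):
    cov = np.diag([1e-6, se**2])
    return EMFit(
        beta=np.array([0.0, coef]),
        beta_names=["intercept", term],
        gamma=np.array([]),
        gamma_names=[],
        covariance=cov,
        loglik_trajectory=np.array([0.0]),
        weights=pd.Series(dtype=float),
        n_iter=1,
        converged=True,
        model_spec=ModelSpec(),
        settings=EMSettings(),
    )


def test_effect_estimate_null_coefficient():
    est = effect_estimate(_fake_fit(0.0, 0.1), "hypoxia")
    assert est.odds_ratio == 1.0
    assert est.p_value == pytest.approx(1.0)


def test_effect_estimate_closed_form():
    est = effect_estimate(_fake_fit(0.25, 0.1), "hypoxia")
    assert est.odds_ratio == pytest.approx(np.exp(0.25))
    assert est.ci_low == pytest.approx(np.exp(0.25 - 1.959964 * 0.1))
    assert est.ci_high == pytest.approx(np.exp(0.25 + 1.959964 * 0.1))
    z = 0.25 / 0.1
    from scipy import stats

    assert est.p_value == pytest.approx(2 * stats.norm.sf(z))


def test_effect_estimate_degenerate_se_collapses_ci():
    est = effect_estimate(_fake_fit(np.log(2.0), 0.0), "hypoxia")
    assert est.ci_low == pytest.approx(2.0)
    assert est.ci_high == pytest.approx(2.0)


def test_effect_estimate_unknown_term():
    with pytest.raises(KeyError):
        effect_estimate(_fake_fit(0.1, 0.1), "smoking")


# ---------------------------------------------------------------------------
# interaction


def test_interaction_saturated_complete_data_equals_ratio_of_sample_ors():
    """With complete data and a saturated gender x exposure x outcome table,
    the interaction MLE is the ratio of the stratum odds ratios."""
    counts = {
        # (gender, x, y): count
        ("male", 1, 1): 30, ("male", 1, 0): 70,
        ("male", 0, 1): 20, ("male", 0, 0): 180,
        ("female", 1, 1): 12, ("female", 1, 0): 88,
        ("female", 0, 1): 25, ("female", 0, 0): 175,
    }
    records = []
    for (g, x, y), k in counts.items():
        records += [
            {"gender": g, "asd": y, "hypoxia": "positive" if x else "negative"}
        ] * k
    table = _no_z_table(records)
    spec = ModelSpec(outcome_terms=("hypoxia",), exposure_terms=())
    est, fit = interaction_fit(table, spec, EMSettings(variance_method="observed_hessian"))

    def or_of(g):
        a = counts[(g, 1, 1)] * counts[(g, 0, 0)]
        b = counts[(g, 1, 0)] * counts[(g, 0, 1)]
        return a / b

    assert est.term == "gender=male:hypoxia"
    assert est.odds_ratio == pytest.approx(or_of("male") / or_of("female"), rel=1e-6)


def test_interaction_requires_both_genders():
    records = [
        {"gender": "male", "asd": y, "hypoxia": h}
        for y, h in [(1, "positive"), (0, "negative"), (0, "positive"), (1, "negative")]
    ]
    table = _no_z_table(records)
    spec = ModelSpec(outcome_terms=("hypoxia",), exposure_terms=())
    with pytest.raises(ValueError, match="gender"):
        interaction_fit(table, spec)


# ---------------------------------------------------------------------------
# sklearn front end


def test_estimator_clone_and_fit():
    est = EMExposureLogit(
        exposure_terms=("maternal_age", "labor_type"),
        outcome_terms=("hypoxia", "gender"),
        r=0.7,
        variance_method="none",
    )
    assert clone(est).get_params() == est.get_params()
    table, _ = _sim(n=400, seed=13)
    est.fit(table)
    assert est.converged_
    assert est.beta_.shape[0] == len(est.coef_names_) - est.gamma_.shape[0]
    proba = est.predict_proba(table)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    effect = est.effect()
    assert effect.term == "hypoxia"


def test_variance_recompute_matches_fit(toy_schema):
    table, config = _sim(n=400, seed=14)
    spec = config.model_spec()
    fit = fit_em(table, spec, EMSettings(variance_method="observed_hessian"))
    cov = variance(fit, table)
    np.testing.assert_allclose(cov, fit.covariance, atol=1e-10)
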