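"""Synthetic perinatal cohorts with the structure the EM estimator assumes.

The generator draws categorical maternal/obstetric covariates Z, a binary
exposure X from a logistic model in Z, and a rare binary outcome Y from a
logistic model in X, gender and confounders W. Missingness is then applied
to X under one of three mechanisms:

* ``mcar`` — a constant miss probability;
* ``mar`` — a logistic miss probability in chosen Z/Y drivers (intercept
  solved so the realized expected rate hits the target);
* ``nmar`` — two independent triggers. The exposure trigger fires with
  probability a if X=1 and b if X=0, solved per subject so that the
  probability ratio r = P(X=1|missing,Z) / P(X=1|observed,Z) — marginally
  over the second trigger — equals the configured target exactly; b is
  tuned so the overall miss rate hits its target. The second, outcome-linked
  trigger makes affected children less likely to go untested, reproducing
  the depressed outcome rate observed among untested children in perinatal
  registries (roughly 0.7 of the tested-group rate); it is the feature that
  gives the sensitivity sweep its characteristic monotone response to r.
  Setting ``outcome_miss_share=0`` disables it, leaving the pure
  exposure-dependent mechanism.

Truth columns (``truth_x``, ``missing_indicator``) are kept so recovery
experiments can score estimates against the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

from ._utils import logistic
from .cohort import NEGATIVE, POSITIVE, CohortSchema, CohortTable, ModelSpec
from .em import EMSettings, complete_case_fit, effect_estimate, fit_em


@dataclass(frozen=True)
class CovariateSpec:
    """One categorical covariate: ordered labels and their probabilities."""

    name: str
    categories: tuple[str, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "probabilities", tuple(float(p) for p in self.probabilities))
        if len(self.categories) != len(self.probabilities):
            raise ValueError(f"{self.name}: categories/probabilities length mismatch")
        if abs(sum(self.probabilities) - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: probabilities must sum to 1")


@dataclass(frozen=True)
class MissingnessSpec:
    """How the exposure goes missing.

    ``target_r`` is required exactly for the nmar mechanism; ``mar_coefs``
    maps design-column or ``asd`` driver names to log-odds effects on the
    miss probability (mar only).
    """

    mechanism: Literal["mcar", "mar", "nmar"]
    target_overall_rate: float
    target_r: float | None = None
    mar_coefs: dict[str, float] | None = None
    outcome_miss_logor: float = -0.65
    outcome_miss_share: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.target_overall_rate < 1.0:
            raise ValueError("target_overall_rate must be in (0, 1)")
        if (self.mechanism == "nmar") != (self.target_r is not None):
            raise ValueError("target_r must be given iff mechanism is nmar")
        if self.target_r is not None and not 0.0 < self.target_r <= 1.0:
            raise ValueError("target_r must be in (0, 1]")
        if not 0.0 <= self.outcome_miss_share < 1.0:
            raise ValueError("outcome_miss_share must be in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to draw one cohort.

    Coefficients are dicts keyed by design-column names (``intercept``,
    ``<covariate>=<category>``, ``gender=male``, the exposure name, and
    optionally ``gender=male:<exposure>``), which keeps them aligned to the
    encoded design by construction.
    """

    n: int
    covariates: tuple[CovariateSpec, ...]
    gamma_true: dict[str, float]
    beta_true: dict[str, float]
    missingness: MissingnessSpec
    seed: int = 0
    p_male: float = 0.512
    exposure: str = "hypoxia"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        for coefs in (self.gamma_true, self.beta_true):
            if "intercept" not in coefs:
                raise ValueError("coefficient dicts must include 'intercept'")

    def schema(self) -> CohortSchema:
        return CohortSchema(covariates={c.name: list(c.categories) for c in self.covariates})

    def true_log_or(self) -> float:
        return float(self.beta_true[self.exposure])

    def model_spec(self) -> ModelSpec:
        """The analysis model matching the generating model."""
        z_terms: list[str] = []
        for key in self.gamma_true:
            if key == "intercept":
                continue
            cov = key.split("=")[0]
            if cov not in z_terms:
                z_terms.append(cov)
        outcome: list[str] = [self.exposure]
        for key in self.beta_true:
            if key in ("intercept", self.exposure):
                continue
            if key == f"gender=male:{self.exposure}":
                outcome.append(f"gender:{self.exposure}")
            elif key == "gender=male":
                outcome.append("gender")
            else:
                cov = key.split("=")[0]
                if cov not in outcome:
                    outcome.append(cov)
        return ModelSpec(
            exposure=self.exposure,
            outcome_terms=tuple(outcome),
            exposure_terms=tuple(z_terms),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "n": self.n,
            "seed": self.seed,
            "p_male": self.p_male,
            "exposure": self.exposure,
            "covariates": [
                {"name": c.name, "categories": list(c.categories), "probabilities": list(c.probabilities)}
                for c in self.covariates
            ],
            "gamma_true": dict(self.gamma_true),
            "beta_true": dict(self.beta_true),
            "missingness": {
                "mechanism": self.missingness.mechanism,
                "target_overall_rate": self.missingness.target_overall_rate,
                "target_r": self.missingness.target_r,
                "mar_coefs": self.missingness.mar_coefs,
                "outcome_miss_logor": self.missingness.outcome_miss_logor,
                "outcome_miss_share": self.missingness.outcome_miss_share,
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        miss = raw["missingness"]
        return cls(
            n=int(raw["n"]),
            covariates=tuple(
                CovariateSpec(c["name"], tuple(c["categories"]), tuple(c["probabilities"]))
                for c in raw["covariates"]
            ),
            gamma_true={k: float(v) for k, v in raw["gamma_true"].items()},
            beta_true={k: float(v) for k, v in raw["beta_true"].items()},
            missingness=MissingnessSpec(
                mechanism=miss["mechanism"],
                target_overall_rate=float(miss["target_overall_rate"]),
                target_r=None if miss.get("target_r") is None else float(miss["target_r"]),
                mar_coefs=miss.get("mar_coefs"),
                outcome_miss_logor=float(miss.get("outcome_miss_logor", -0.65)),
                outcome_miss_share=float(miss.get("outcome_miss_share", 0.5)),
            ),
            seed=int(raw.get("seed", 0)),
            p_male=float(raw.get("p_male", 0.512)),
            exposure=raw.get("exposure", "hypoxia"),
        )


# ---------------------------------------------------------------------------
# linear predictors from coefficient dicts


def _eta(df: pd.DataFrame, coefs: dict[str, float], x: np.ndarray | None = None, exposure: str = "hypoxia") -> np.ndarray:
    eta = np.full(len(df), coefs.get("intercept", 0.0))
    for key, coef in coefs.items():
        if key == "intercept":
            continue
        if key == exposure:
            eta += coef * x
        elif key == f"gender=male:{exposure}":
            eta += coef * (df["gender"] == "male").to_numpy(float) * x
        elif key == "asd":
            eta += coef * df["asd"].to_numpy(float)
        elif "=" in key:
            col, cat = key.split("=", 1)
            eta += coef * (df[col] == cat).to_numpy(float)
        else:
            raise KeyError(f"cannot interpret coefficient key {key!r}")
    return eta


# ---------------------------------------------------------------------------
# missingness machinery


def _r_of_a(a: np.ndarray, b: float, pi: np.ndarray) -> np.ndarray:
    """The probability ratio r implied by miss rates (a, b) at exposure
    probability pi."""
    p1_miss = a * pi / (a * pi + b * (1.0 - pi))
    p1_obs = (1.0 - a) * pi / ((1.0 - a) * pi + (1.0 - b) * (1.0 - pi))
    return p1_miss / p1_obs


def _solve_a(
    pi: np.ndarray, b: float | np.ndarray, target_r: float, tol: float = 1e-10
) -> np.ndarray:
    """Vectorized bisection for a = P(miss | X=1) hitting the target ratio."""
    lo = np.full_like(pi, 1e-12)
    hi = np.full_like(pi, 1.0 - 1e-12)
    r_lo = _r_of_a(lo, b, pi)
    r_hi = _r_of_a(hi, b, pi)
    if np.any(r_lo > target_r) or np.any(r_hi < target_r):
        raise ValueError(
            f"no miss rate a in (0,1) achieves r={target_r} at b={b}: "
            f"feasible r range is ({float(r_lo.max()):.3g}, {float(r_hi.min()):.3g})"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        too_high = _r_of_a(mid, b, pi) > target_r
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
        if np.max(hi - lo) < tol:
            break
    return 0.5 * (lo + hi)


def solve_missingness_rates(pi: float, base_rate_b: float, target_r: float) -> tuple[float, float]:
    """Solve P(miss | X=1) = a given P(miss | X=0) = b and a target ratio r.

    r is the ratio of the conditional exposure probabilities in the missing
    versus observed groups; r(a=b) = 1 and r is increasing in a, so a
    unique root exists for any attainable target. Bisection to 1e-10.
    """
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must be in (0, 1)")
    if not 0.0 < base_rate_b < 1.0:
        raise ValueError("base_rate_b must be in (0, 1)")
    if not 0.0 < target_r <= 1.0:
        raise ValueError("target_r must be in (0, 1]")
    a = _solve_a(np.asarray([pi]), base_rate_b, target_r)
    return float(a[0]), float(base_rate_b)


def _miss_probabilities(
    df: pd.DataFrame,
    x: np.ndarray,
    pi: np.ndarray,
    mu1: np.ndarray,
    mu0: np.ndarray,
    spec: MissingnessSpec,
    exposure: str,
) -> np.ndarray:
    target = spec.target_overall_rate
    if spec.mechanism == "mcar":
        return np.full(len(df), target)
    if spec.mechanism == "mar":
        coefs = dict(spec.mar_coefs or {})
        coefs.pop("intercept", None)
        slope_eta = _eta(df, {"intercept": 0.0, **coefs}, exposure=exposure)
        c = optimize.brentq(
            lambda c0: float(np.mean(logistic(c0 + slope_eta))) - target, -30.0, 30.0
        )
        return logistic(c + slope_eta)

    # nmar: exposure trigger OR outcome-linked trigger. The outcome trigger
    # q(Y) carries `outcome_miss_share` of the target rate; the exposure
    # trigger's per-subject rates are solved so the total miss probability
    # given X (marginal over Y) hits the target probability ratio exactly.
    y = df["asd"].to_numpy(float)
    if spec.outcome_miss_share > 0:
        delta = spec.outcome_miss_logor
        c2 = optimize.brentq(
            lambda c0: float(np.mean(logistic(c0 + delta * y)))
            - spec.outcome_miss_share * target,
            -30.0,
            30.0,
        )
        q_y = logistic(c2 + delta * y)
        q1 = logistic(c2 + delta)  # q given Y=1
        q0 = logistic(c2)
    else:
        q_y = np.zeros(len(df))
        q1 = q0 = 0.0
    # expected outcome-trigger rate given X, before Y is seen
    qbar1 = q1 * mu1 + q0 * (1.0 - mu1)
    qbar0 = q1 * mu0 + q0 * (1.0 - mu0)

    def totals(b_chan: float) -> tuple[np.ndarray, np.ndarray]:
        m0 = 1.0 - (1.0 - b_chan) * (1.0 - qbar0)
        m1 = _solve_a(pi, m0, spec.target_r)
        return m1, m0

    def overall(b_chan: float) -> float:
        m1, m0 = totals(b_chan)
        return float(np.mean(m1 * pi + m0 * (1.0 - pi))) - target

    b_chan = optimize.brentq(overall, 1e-6, 1.0 - 1e-6, xtol=1e-10)
    m1, m0 = totals(b_chan)
    # back out the exposure-trigger rate for X=1 from the required total
    a_chan = 1.0 - (1.0 - m1) / (1.0 - qbar1)
    if np.any(a_chan < -1e-9):
        raise ValueError(
            "infeasible nmar configuration: outcome trigger alone exceeds the "
            "total miss rate required for the target ratio; lower "
            "outcome_miss_share or raise target_r"
        )
    a_chan = np.clip(a_chan, 0.0, 1.0 - 1e-12)
    chan_x = np.where(x == 1, a_chan, b_chan)
    return 1.0 - (1.0 - chan_x) * (1.0 - q_y)


# ---------------------------------------------------------------------------
# cohort generation


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> CohortTable:
    """Draw one cohort; deterministic given the seed.

    The returned table carries the observable columns plus ``truth_x`` and
    ``missing_indicator``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n
    data: dict[str, object] = {
        "id": [f"s{i:07d}" for i in range(n)],
        "gender": np.where(rng.random(n) < config.p_male, "male", "female"),
    }
    for cov in config.covariates:
        data[cov.name] = rng.choice(cov.categories, size=n, p=cov.probabilities)
    df = pd.DataFrame(data)

    pi = logistic(_eta(df, config.gamma_true, exposure=config.exposure))
    x = (rng.random(n) < pi).astype(int)
    mu1 = logistic(_eta(df, config.beta_true, x=np.ones(n), exposure=config.exposure))
    mu0 = logistic(_eta(df, config.beta_true, x=np.zeros(n), exposure=config.exposure))
    mu = np.where(x == 1, mu1, mu0)
    df["asd"] = (rng.random(n) < mu).astype(int)

    p_miss = _miss_probabilities(df, x, pi, mu1, mu0, config.missingness, config.exposure)
    missing = rng.random(n) < p_miss
    df["hypoxia"] = np.where(missing, None, np.where(x == 1, POSITIVE, NEGATIVE))
    df["truth_x"] = x
    df["missing_indicator"] = missing.astype(int)
    return CohortTable(df=df, schema=config.schema())


def empirical_r(table: CohortTable, by: Sequence[str] | None = None) -> float:
    """The realized probability ratio r from the truth columns.

    Crude by default; with ``by`` the ratio is computed within covariate
    strata and averaged weighted by stratum size (strata with an empty
    missing or observed group are skipped).
    """
    if not table.has_truth:
        raise ValueError("table lacks truth columns; only simulated cohorts support this")
    df = table.df

    def crude(sub: pd.DataFrame) -> float:
        miss = sub[sub["missing_indicator"] == 1]
        obs = sub[sub["missing_indicator"] == 0]
        if miss.empty or obs.empty:
            raise ValueError("empty missing or observed group")
        p_miss = miss["truth_x"].mean()
        p_obs = obs["truth_x"].mean()
        if p_obs == 0:
            raise ValueError("no exposed subjects among observed records")
        return float(p_miss / p_obs)

    if by is None:
        return crude(df)
    total = 0.0
    weight = 0.0
    for _, sub in df.groupby(list(by), observed=True):
        try:
            r_s = crude(sub)
        except ValueError:
            continue
        total += len(sub) * r_s
        weight += len(sub)
    if weight == 0:
        raise ValueError("no stratum had both missing and observed records")
    return total / weight


# ---------------------------------------------------------------------------
# default configurations


def _calibrate_intercept(eta_no_intercept: np.ndarray, target: float) -> float:
    """Intercept making the mean response probability equal the target."""
    return float(
        optimize.brentq(
            lambda c: float(np.mean(logistic(c + eta_no_intercept))) - target, -30.0, 10.0
        )
    )


def _calibrated(config: SimulationConfig, exposure_prevalence: float, outcome_rate: float,
                n_cal: int = 200_000) -> SimulationConfig:
    """Solve the two model intercepts against a large fixed calibration draw."""
    cal = replace(
        config,
        n=n_cal,
        missingness=MissingnessSpec("mcar", 0.5),
        gamma_true={**config.gamma_true, "intercept": 0.0},
        beta_true={**config.beta_true, "intercept": 0.0},
    )
    rng = np.random.default_rng(987654321)
    data = {"gender": np.where(rng.random(n_cal) < cal.p_male, "male", "female")}
    for cov in cal.covariates:
        data[cov.name] = rng.choice(cov.categories, size=n_cal, p=cov.probabilities)
    df = pd.DataFrame(data)
    gamma = dict(config.gamma_true)
    gamma["intercept"] = _calibrate_intercept(
        _eta(df, {**gamma, "intercept": 0.0}, exposure=config.exposure), exposure_prevalence
    )
    pi = logistic(_eta(df, gamma, exposure=config.exposure))
    x = (rng.random(n_cal) < pi).astype(float)
    beta = dict(config.beta_true)
    beta["intercept"] = _calibrate_intercept(
        _eta(df, {**beta, "intercept": 0.0}, x=x, exposure=config.exposure), outcome_rate
    )
    return replace(config, gamma_true=gamma, beta_true=beta)


def default_config(
    n: int = 20_000,
    missingness: MissingnessSpec | None = None,
    true_or: float = 1.5,
    seed: int = 0,
) -> SimulationConfig:
    """The reference cohort: eight categorical covariates driving a 14%
    exposure, a 0.5% outcome with a roughly 5:1 male excess, and 52%
    missing exposure by default (the scale of the motivating registry)."""
    covariates = (
        CovariateSpec("maternal_age", ("25-30", "<=25", "30-35", ">35"), (0.35, 0.22, 0.30, 0.13)),
        CovariateSpec("parity", ("0", "1", "2", "3", "4+"), (0.42, 0.33, 0.15, 0.06, 0.04)),
        CovariateSpec("smoking", ("no", "yes"), (0.82, 0.18)),
        CovariateSpec("preeclampsia", ("no", "yes"), (0.97, 0.03)),
        CovariateSpec("presentation", ("cephalic", "breech"), (0.96, 0.04)),
        CovariateSpec("labor_type", ("spontaneous", "induced", "c-section"), (0.58, 0.27, 0.15)),
        CovariateSpec("apgar_low", ("no", "yes"), (0.98, 0.02)),
        CovariateSpec("birth_weight", ("2.5-4.5", "<2.5", ">4.5"), (0.92, 0.06, 0.02)),
    )
    gamma = {
        "intercept": 0.0,  # calibrated below
        "maternal_age=<=25": 0.10,
        "maternal_age=30-35": 0.05,
        "maternal_age=>35": 0.15,
        "parity=1": -0.10,
        "parity=2": -0.15,
        "parity=3": -0.15,
        "parity=4+": -0.10,
        "smoking=yes": 0.20,
        "preeclampsia=yes": 0.80,
        "presentation=breech": 0.60,
        "labor_type=induced": 0.30,
        "labor_type=c-section": 0.50,
        "apgar_low=yes": 1.20,
        "birth_weight=<2.5": 0.70,
        "birth_weight=>4.5": 0.30,
    }
    beta = {
        "intercept": 0.0,  # calibrated below
        "hypoxia": float(np.log(true_or)),
        "gender=male": float(np.log(5.0)),
    }
    if missingness is None:
        missingness = MissingnessSpec(
            mechanism="mar",
            target_overall_rate=0.52,
            mar_coefs={
                "labor_type=induced": -0.3,
                "labor_type=c-section": -0.8,
                "apgar_low=yes": -1.5,
                "presentation=breech": -0.5,
            },
        )
    config = SimulationConfig(
        n=n,
        covariates=covariates,
        gamma_true=gamma,
        beta_true=beta,
        missingness=missingness,
        seed=seed,
    )
    return _calibrated(config, exposure_prevalence=0.14, outcome_rate=0.005)


def compact_config(
    n: int = 20_000,
    missingness: MissingnessSpec | None = None,
    true_or: float = 1.5,
    outcome_rate: float = 0.01,
    seed: int = 0,
) -> SimulationConfig:
    """A two-covariate cohort for repeated-fit experiments.

    Same statistical structure as :func:`default_config` (categorical Z
    driving a 14% exposure, rare outcome with male excess, controllable
    missingness) but a small design, so hundreds of replicate fits stay
    cheap.
    """
    covariates = (
        CovariateSpec("maternal_age", ("25-30", "<=25", "30-35", ">35"), (0.35, 0.22, 0.30, 0.13)),
        CovariateSpec("labor_type", ("spontaneous", "induced", "c-section"), (0.58, 0.27, 0.15)),
    )
    gamma = {
        "intercept": 0.0,
        "maternal_age=>35": 0.30,
        "labor_type=induced": 0.40,
        "labor_type=c-section": 0.80,
    }
    beta = {
        "intercept": 0.0,
        "hypoxia": float(np.log(true_or)),
        "gender=male": float(np.log(5.0)),
    }
    if missingness is None:
        missingness = MissingnessSpec(
            mechanism="mar",
            target_overall_rate=0.50,
            mar_coefs={"labor_type=induced": -0.3, "labor_type=c-section": -0.7},
        )
    config = SimulationConfig(
        n=n,
        covariates=covariates,
        gamma_true=gamma,
        beta_true=beta,
        missingness=missingness,
        seed=seed,
    )
    return _calibrated(config, exposure_prevalence=0.14, outcome_rate=outcome_rate)


# ---------------------------------------------------------------------------
# recovery experiments


@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo summary of repeated simulate-then-fit experiments."""

    n_reps: int
    n_converged: int
    true_log_or: float
    mean_log_or: float
    bias: float
    empirical_se: float
    coverage: float
    complete_case_mean_log_or: float
    complete_case_bias: float
    estimates: tuple[float, ...] = field(repr=False)

    @property
    def se_of_mean(self) -> float:
        return self.empirical_se / np.sqrt(max(self.n_converged, 1))


def recovery_experiment(
    config: SimulationConfig,
    n_reps: int,
    fit_settings: EMSettings | None = None,
) -> RecoverySummary:
    """Simulate and refit ``n_reps`` cohorts; score against the truth.

    Per-replicate seeds are ``config.seed + rep``. Reports the exposure
    log-odds-ratio bias, empirical SE, 95% Wald CI coverage, and the
    complete-case comparator fitted on observed-exposure records only.
    Non-converged replicates are excluded from the summary (their count is
    carried in ``n_converged``).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    fit_settings = fit_settings or EMSettings()
    spec = config.model_spec()
    truth = config.true_log_or()
    estimates: list[float] = []
    covered: list[bool] = []
    cc_estimates: list[float] = []
    for rep in range(n_reps):
        table = simulate_cohort(config, seed=config.seed + rep)
        fit = fit_em(table, spec, fit_settings)
        if not fit.converged:
            continue
        est = effect_estimate(fit, config.exposure)
        log_or = float(np.log(est.odds_ratio))
        estimates.append(log_or)
        covered.append(est.ci_low <= np.exp(truth) <= est.ci_high)
        cc = complete_case_fit(table, spec)
        cc_estimates.append(float(cc.coefficients[cc.names.index(config.exposure)]))
    if len(estimates) < 2:
        raise RuntimeError("fewer than 2 converged replicates; cannot summarize")
    arr = np.asarray(estimates)
    cc_arr = np.asarray(cc_estimates)
    return RecoverySummary(
        n_reps=n_reps,
        n_converged=len(estimates),
        true_log_or=truth,
        mean_log_or=float(arr.mean()),
        bias=float(arr.mean() - truth),
        empirical_se=float(arr.std(ddof=1)),
        coverage=float(np.mean(covered)),
        complete_case_mean_log_or=float(cc_arr.mean()),
        complete_case_bias=float(cc_arr.mean() - truth),
        estimates=tuple(estimates),
    )
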