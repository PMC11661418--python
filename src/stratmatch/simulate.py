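"""Seeded generator of confounded observational survival cohorts.

The generator emulates the statistical structure the matching method
assumes: ~1,800 patients with ~10 mixed-type prognostic covariates,
treatment assignment confounded with prognosis through a logistic
propensity on the covariates, proportional-hazards survival times with a
Weibull baseline, and independent uniform-window right-censoring
calibrated to a target rate. Treated patients carry *more favorable*
covariate profiles by default, mirroring how adjuvant therapy is
preferentially given to fitter patients in observational series.

Ground truth (true coefficients, linear predictors and horizon risks) is
returned alongside the cohort so that recovery tests can check the whole
pipeline against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, CovariateSchema

DEFAULT_HORIZON = 60.0  # months; 5-year endpoint


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    ``beta_outcome`` are true log-hazard coefficients and
    ``gamma_propensity`` treatment log-odds coefficients, both over the
    *encoded* covariates (continuous + binary + per-non-reference-level
    categorical indicators); ``None`` selects defaults in which prognosis
    and treatment propensity are negatively aligned (confounding by
    indication toward healthier treated patients).
    """

    n: int = 1800
    k_continuous: int = 4
    k_binary: int = 4
    k_categorical: int = 2
    categorical_levels: int = 3
    binary_prevalence: float | np.ndarray = 0.4
    beta_outcome: Optional[np.ndarray] = None
    gamma_propensity: Optional[np.ndarray] = None
    propensity_intercept: float = 0.7
    treatment_effect: float = -0.3
    treatment_effect_sd: float = 0.0
    weibull_shape: float = 1.0
    baseline_5yr_survival: float = 0.5
    censoring_rate: float = 0.35
    horizon: float = DEFAULT_HORIZON
    seed: int = 0
    confounding_scale: float = 1.0
    interaction_strength: float = 0.0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring rate must be in [0, 1)")
        K = self.n_encoded
        if self.beta_outcome is None:
            base = np.array(
                [0.45, -0.35, 0.3, -0.25, 0.5, -0.4, 0.35, -0.3, 0.4, 0.25, -0.35, 0.3]
            )
            self.beta_outcome = np.resize(base, K)
        if self.gamma_propensity is None:
            # negatively aligned with prognosis: healthier patients treated
            self.gamma_propensity = -0.8 * np.asarray(self.beta_outcome)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.gamma_propensity = self.confounding_scale * np.asarray(
            self.gamma_propensity, dtype=float
        )
        if len(self.beta_outcome) != K or len(self.gamma_propensity) != K:
            raise ValueError(f"coefficient vectors must have length {K}")

    @property
    def n_encoded(self) -> int:
        return (
            self.k_continuous
            + self.k_binary
            + self.k_categorical * (self.categorical_levels - 1)
        )

    @property
    def schema(self) -> tuple:
        cov = [
            CovariateSchema(f"x{i+1}", "continuous") for i in range(self.k_continuous)
        ]
        cov += [CovariateSchema(f"b{i+1}", "binary") for i in range(self.k_binary)]
        cov += [
            CovariateSchema(
                f"c{i+1}",
                "categorical",
                tuple(f"L{j}" for j in range(self.categorical_levels)),
            )
            for i in range(self.k_categorical)
        ]
        return tuple(cov)


def _weibull_scale(config: GeneratorConfig) -> float:
    """Baseline scale lambda with S0(horizon) = baseline_5yr_survival."""
    return config.horizon / (-np.log(config.baseline_5yr_survival)) ** (
        1.0 / config.weibull_shape
    )


def generate_cohort(config: GeneratorConfig) -> tuple:
    """Draw a confounded cohort; returns ``(Cohort, truth)``.

    ``truth`` records the encoded design matrix, true coefficients, linear
    predictors, true no-treatment horizon risks, uncensored event times and
    the achieved censoring rate.
    """
    rng = np.random.default_rng(config.seed)
    n, shape = config.n, config.weibull_shape
    scale = _weibull_scale(config)

    cols, enc_cols = {}, []
    for i in range(config.k_continuous):
        v = rng.normal(size=n)
        cols[f"x{i+1}"] = v
        enc_cols.append(v)
    prev = np.broadcast_to(
        np.atleast_1d(np.asarray(config.binary_prevalence, dtype=float)),
        (config.k_binary,),
    )
    for i in range(config.k_binary):
        v = rng.binomial(1, prev[i], size=n).astype(float)
        cols[f"b{i+1}"] = v
        enc_cols.append(v)
    for i in range(config.k_categorical):
        L = config.categorical_levels
        draws = rng.integers(0, L, size=n)
        cols[f"c{i+1}"] = pd.Categorical.from_codes(
            draws, categories=[f"L{j}" for j in range(L)]
        ).astype(str)
        for j in range(1, L):
            enc_cols.append((draws == j).astype(float))
    Z = np.column_stack(enc_cols)

    logit = config.propensity_intercept + Z @ config.gamma_propensity
    a = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit)))

    # optional stratum-heterogeneous hazard: pairwise products of the first
    # continuous covariates enter the true log hazard but not the schema the
    # models see, so the covariate-outcome relation varies across the risk
    # range and any linear fit is a training-distribution-weighted projection
    lp_base = Z @ config.beta_outcome
    if config.interaction_strength != 0.0 and config.k_continuous >= 2:
        kappa = config.interaction_strength
        inter = np.zeros(n)
        for i in range(0, config.k_continuous - 1, 2):
            inter += Z[:, i] * Z[:, i + 1]
        lp_base = lp_base + kappa * inter
    # heterogeneous treatment response: each treated patient draws an
    # individual log-hazard shift around the average effect (unobservable to
    # any fitted model, so treated outcomes are intrinsically noisier)
    effect = config.treatment_effect + config.treatment_effect_sd * rng.normal(size=n)
    lp = lp_base + effect * a
    # inverse transform for Weibull PH: S(t|x) = exp(-(t/scale)^shape * e^lp)
    u = rng.uniform(size=n)
    T = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)

    u_c = rng.uniform(size=n)
    if config.censoring_rate > 0:
        w = _calibrate_censoring_window(T, u_c, config.censoring_rate)
        C = w * u_c
    else:
        C = np.full(n, np.inf)
    t_obs = np.minimum(T, C)
    y = (T <= C).astype(int)
    achieved = 1.0 - y.mean()
    if config.censoring_rate > 0 and abs(achieved - config.censoring_rate) > 0.05:
        import logging

        logging.getLogger(__name__).warning(
            "achieved censoring rate %.3f vs target %.3f", achieved, config.censoring_rate
        )

    lp_untreated = lp_base
    true_risk = 1.0 - np.exp(
        -((config.horizon / scale) ** shape) * np.exp(lp_untreated)
    )
    cohort = Cohort(
        ids=np.arange(n),
        X=pd.DataFrame(cols),
        a=a,
        t=t_obs,
        y=y,
        schema=config.schema,
    )
    truth = {
        "Z": Z,
        "beta_outcome": config.beta_outcome,
        "gamma_propensity": config.gamma_propensity,
        "treatment_effect": config.treatment_effect,
        "lp": lp,
        "lp_untreated": lp_untreated,
        "true_risk": true_risk,
        "event_time": T,
        "weibull_scale": scale,
        "achieved_censoring": achieved,
    }
    return cohort, truth


def _calibrate_censoring_window(T, u_c, target: float) -> float:
    """Bisect the censoring window width so mean(T > w*u) hits the target."""
    lo, hi = 1e-6, 1.0
    while np.mean(T > hi * u_c) > target and hi < 1e9:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(T > mid * u_c) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_matching_instance(
    m: int, n: int, alpha: int = None, seed: int = 0, planted: bool = False
):
    """Random (or planted-optimum) bipartite distance instance for solver tests.

    With ``planted=True`` the diagonal carries small distances and the rest
    large ones, so the identity pairing is the known optimum by
    construction.
    """
    from .matching import MatchingInstance

    rng = np.random.default_rng(seed)
    if planted:
        D = rng.uniform(5.0, 10.0, size=(m, n))
        d = min(m, n)
        D[np.arange(d), np.arange(d)] = rng.uniform(0.0, 0.5, size=d)
    else:
        D = rng.uniform(0.0, 5.0, size=(m, n))
    if alpha is None:
        alpha = min(m, n)
    return MatchingInstance(
        stratum_index=1,
        A_ids=np.arange(m),
        B_ids=np.arange(n),
        D=D,
        alpha=alpha,
    )
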