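"""Cox model fitting and the model-suite orchestration.

``fit_cox`` wraps a proportional-hazards fit (partial likelihood with
Efron tie handling, Breslow baseline survival) behind a :class:`CoxFit`
that predicts absolute event risk at a horizon. ``build_model_suite``
trains the full comparison family on one cohort:

* ``model1`` — entire cohort, treatment included as a binary covariate;
* ``model2A`` / ``model2B`` — untreated / treated sub-cohorts;
* ``model3A`` / ``model3B`` — stratum-matched sub-cohorts (two-stage
  mechanism), optionally oversampled;
* ``psmA`` / ``psmB`` — propensity-score-matched sub-cohorts.

All models other than ``model1`` exclude the treatment column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .cohort import Cohort, CovariateSchema, encode

logger = logging.getLogger(__name__)

TREATMENT_COL = "treatment"


class ModelingError(ValueError):
    """Fit preconditions violated or optimizer failure."""


@dataclass
class CoxFit:
    """A fitted proportional-hazards model with its Breslow baseline.

    ``coefficients`` are per-encoded-covariate log hazard ratios; risk at a
    horizon h is ``1 - S0(h) ** exp(lp)`` with the linear predictor
    centered at the training covariate means (the centering is absorbed
    into the stored baseline).
    """

    model: CoxPHFitter
    schema: Sequence[CovariateSchema]
    includes_treatment: bool
    n_training_rows: int

    @property
    def coefficients(self) -> pd.Series:
        return self.model.params_

    def design_matrix(self, cohort: Cohort) -> pd.DataFrame:
        Z = encode(cohort).Z
        if self.includes_treatment:
            Z[TREATMENT_COL] = cohort.a.astype(float)
        return Z

    def linear_predictor(self, cohort: Cohort) -> np.ndarray:
        """Uncentered linear predictor beta'x on the raw encoded scale."""
        Z = self.design_matrix(cohort)
        return Z[self.coefficients.index].to_numpy() @ self.coefficients.to_numpy()

    def baseline_survival_at(self, horizon: float) -> float:
        bs = self.model.baseline_survival_
        support = bs.index.to_numpy()
        if horizon > support.max():
            logger.warning(
                "horizon %.1f beyond baseline support %.1f; using last value",
                horizon,
                support.max(),
            )
        idx = np.searchsorted(support, horizon, side="right") - 1
        if idx < 0:
            return 1.0
        return float(bs.iloc[idx, 0])

    def predict_risk(self, cohort: Cohort, horizon: float) -> np.ndarray:
        return predict_risk(self, cohort, horizon)


def fit_cox(
    cohort: Cohort,
    include_treatment: bool = False,
    penalizer: float = 0.0,
    initial_point: np.ndarray = None,
    precision: float = 1e-10,
) -> CoxFit:
    """Fit a Cox model on a (possibly duplicated) row multiset.

    Raises :class:`ModelingError` when there are no events, when a design
    column is constant (degenerate: no information for its coefficient),
    or when the partial-likelihood optimizer fails to converge.
    """
    if cohort.y.sum() == 0:
        raise ModelingError("cannot fit a Cox model: no events observed")
    Z = encode(cohort).Z
    if include_treatment:
        Z[TREATMENT_COL] = cohort.a.astype(float)
    degenerate = [c for c in Z.columns if Z[c].nunique() <= 1]
    if degenerate:
        raise ModelingError(f"zero-variance design columns: {degenerate}")
    df = Z.copy()
    df["_t"] = cohort.t
    df["_y"] = cohort.y
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="_t",
                event_col="_y",
                initial_point=initial_point,
                fit_options={"precision": precision},
            )
    except ConvergenceError as exc:
        raise ModelingError(f"Cox fit did not converge: {exc}") from exc
    return CoxFit(
        model=cph,
        schema=cohort.schema,
        includes_treatment=include_treatment,
        n_training_rows=cohort.n,
    )


def predict_risk(fit: CoxFit, cohort: Cohort, horizon: float) -> np.ndarray:
    """Probability of the event by ``horizon``: 1 - S0(h)^exp(centered lp)."""
    surv = fit.model.predict_survival_function(
        fit.design_matrix(cohort), times=[horizon]
    )
    risk = 1.0 - surv.iloc[0].to_numpy(dtype=float)
    return np.clip(risk, 0.0, 1.0)


@dataclass
class SuiteConfig:
    """Configuration of the model-suite pipeline."""

    horizon: float = 60.0
    n_strata: int = 10
    alpha_cutoff: int = 20
    variant: str = "equalized"  # stratum matching: 'equalized' or 'relaxed'
    oversample_factor: int = 1
    psm_method: str = "glm"  # 'glm' (caliper 0.2) or 'rf' (no caliper)
    psm_caliper: Optional[float] = 0.2
    seed: int = 0


@dataclass
class ModelSuite:
    """The fitted comparison family plus pipeline artifacts."""

    fits: dict
    training_sizes: dict
    assignment: object
    matched: object
    psm_matched: object

    def __getitem__(self, name: str) -> CoxFit:
        return self.fits[name]


def build_model_suite(cohort: Cohort, config: SuiteConfig = None) -> ModelSuite:
    """Train models 1, 2A/2B, 3A/3B and PSM A/B on one cohort."""
    from . import psm as psm_mod
    from . import stratify as strat_mod
    from .cohort import split_by_treatment
    from .matching import match_stratified_cohort, oversample

    config = config or SuiteConfig()
    untreated, treated = split_by_treatment(cohort)
    fits, sizes = {}, {}

    def _fit(name, subcohort, include_treatment=False):
        try:
            fits[name] = fit_cox(subcohort, include_treatment=include_treatment)
        except ModelingError as exc:
            raise ModelingError(f"stage {name!r}: {exc}") from exc
        sizes[name] = subcohort.n

    _fit("model1", cohort, include_treatment=True)
    _fit("model2A", untreated)
    _fit("model2B", treated)

    assignment = strat_mod.stratify_cohort(
        cohort,
        horizon=config.horizon,
        n_strata=config.n_strata,
        alpha_cutoff=config.alpha_cutoff,
    )
    matched = match_stratified_cohort(cohort, assignment, variant=config.variant)
    matched_os = oversample(matched, config.oversample_factor)
    _fit("model3A", matched_os.untreated)
    _fit("model3B", matched_os.treated)

    prop = psm_mod.estimate_propensity(cohort, method=config.psm_method, seed=config.seed)
    caliper = config.psm_caliper if config.psm_method == "glm" else None
    psm_matched = psm_mod.nearest_neighbor_match(prop, cohort, caliper=caliper)
    _fit("psmA", psm_matched.untreated)
    _fit("psmB", psm_matched.treated)

    return ModelSuite(
        fits=fits,
        training_sizes=sizes,
        assignment=assignment,
        matched=matched_os,
        psm_matched=psm_matched,
    )
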