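"""Stage-1 risk engine: baseline Cox fit, horizon risk, fixed-width strata, alpha.

The baseline prognostic model is fit on *untreated* patients only (and
never sees the treatment column), so the predicted 5-year mortality risks
are counterfactual no-treatment risks for everyone. Risks are binned into
S fixed-width probability strata of width 1/S — stratum 3 covers risk
[0.2, 0.3) when S=10 — and the per-stratum matching quota alpha is the
smallest stratum-by-arm patient count that still reaches the cutoff
(default 20).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, split_by_treatment
from .modeling import CoxFit, ModelingError, fit_cox, predict_risk

logger = logging.getLogger(__name__)


class StratificationError(ValueError):
    pass


@dataclass
class StratumAssignment:
    """Per-patient risk and stratum plus the equalization threshold."""

    risk: np.ndarray  # P(event by horizon), in [0, 1]
    stratum: np.ndarray  # integers 1..n_strata
    alpha: int
    census: pd.DataFrame  # n_strata x 2 counts, columns 'untreated', 'treated'
    n_strata: int = 10


def fit_baseline_risk_model(untreated: Cohort, min_per_param: int = 10) -> CoxFit:
    """Fit the stage-1 prognostic Cox model on the untreated arm.

    Guards: at least one event, and enough patients relative to the number
    of encoded covariates (n >= K + ``min_per_param``).
    """
    from .cohort import encode

    if (untreated.a == 1).any():
        raise StratificationError("baseline risk model must be fit on untreated patients")
    K = encode(untreated).K
    if untreated.n < K + min_per_param:
        raise StratificationError(
            f"too few untreated patients ({untreated.n}) for {K} covariates"
        )
    try:
        return fit_cox(untreated, include_treatment=False)
    except ModelingError as exc:
        raise StratificationError(f"baseline risk model: {exc}") from exc


def predict_five_year_risk(model: CoxFit, cohort: Cohort, horizon: float) -> np.ndarray:
    """Counterfactual no-treatment risk of death by the horizon, in [0, 1]."""
    return predict_risk(model, cohort, horizon)


def assign_strata(risks: np.ndarray, n_strata: int = 10) -> np.ndarray:
    """Fixed-width bins: stratum = floor(risk * S) + 1, last bin closed above."""
    risks = np.asarray(risks, dtype=float)
    if (risks < 0).any() or (risks > 1).any():
        raise StratificationError("risks must lie in [0, 1]")
    return np.minimum(np.floor(risks * n_strata).astype(int) + 1, n_strata)


def stratum_census(stratum: np.ndarray, a: np.ndarray, n_strata: int = 10) -> pd.DataFrame:
    """S x 2 table of distinct-patient counts by stratum and treatment arm."""
    stratum = np.asarray(stratum)
    a = np.asarray(a)
    idx = pd.RangeIndex(1, n_strata + 1, name="stratum")
    out = pd.DataFrame(0, index=idx, columns=["untreated", "treated"])
    for s in range(1, n_strata + 1):
        out.loc[s, "untreated"] = int(((stratum == s) & (a == 0)).sum())
        out.loc[s, "treated"] = int(((stratum == s) & (a == 1)).sum())
    return out


def select_alpha(census: pd.DataFrame, cutoff: int = 20) -> int:
    """Smallest nonzero stratum-by-arm count that is >= the cutoff."""
    counts = census.to_numpy().ravel()
    eligible = counts[(counts > 0) & (counts >= cutoff)]
    if len(eligible) == 0:
        raise StratificationError(
            f"no stratum-by-arm subgroup reaches the cutoff {cutoff}; "
            "consider coarser strata"
        )
    return int(eligible.min())


def stratify_cohort(
    cohort: Cohort,
    horizon: float = 60.0,
    n_strata: int = 10,
    alpha_cutoff: int = 20,
) -> StratumAssignment:
    """Full stage 1: baseline fit on untreated, risks, strata, census, alpha."""
    untreated, _ = split_by_treatment(cohort)
    model = fit_baseline_risk_model(untreated)
    risk = predict_five_year_risk(model, cohort, horizon)
    stratum = assign_strata(risk, n_strata)
    census = stratum_census(stratum, cohort.a, n_strata)
    alpha = select_alpha(census, cutoff=alpha_cutoff)
    logger.info("selected alpha=%d over census\n%s", alpha, census)
    return StratumAssignment(
        risk=risk, stratum=stratum, alpha=alpha, census=census, n_strata=n_strata
    )
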