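"""Propensity-score matching comparator: 1:1 nearest neighbor without replacement.

Propensity scores come from either an unpenalized logistic regression
(``glm``) or a random forest (``rf``) of treatment on the encoded
covariates. Matching is greedy nearest-neighbor on the *logit* of the
score, iterating the minority arm in descending score order, each
majority patient usable once; with a caliper (GLM convention), pairs
whose logit distance exceeds ``caliper * SD(logit scores)`` are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .cohort import Cohort, encode
from .matching import MatchedCohorts

logger = logging.getLogger(__name__)

SCORE_CLIP = 1e-6


class PSMError(ValueError):
    pass


@dataclass
class PropensityFit:
    """Estimated per-patient treatment probabilities, clipped inside (0, 1)."""

    scores: np.ndarray
    method: str
    model: object

    @property
    def logit(self) -> np.ndarray:
        return np.log(self.scores / (1.0 - self.scores))


def estimate_propensity(cohort: Cohort, method: str = "glm", seed: int = 0) -> PropensityFit:
    """Fit P(treated | covariates) with a GLM or a 500-tree random forest."""
    if method not in ("glm", "rf"):
        raise PSMError(f"unknown propensity method {method!r}")
    if cohort.a.sum() == 0 or cohort.a.sum() == cohort.n:
        raise PSMError("both treatment arms must be nonempty")
    Z = encode(cohort).Z.to_numpy()
    if method == "glm":
        model = LogisticRegression(C=np.inf, max_iter=5000)  # unpenalized GLM
    else:
        model = RandomForestClassifier(n_estimators=500, random_state=seed)
    model.fit(Z, cohort.a)
    scores = model.predict_proba(Z)[:, 1]
    n_clipped = int(((scores < SCORE_CLIP) | (scores > 1 - SCORE_CLIP)).sum())
    if n_clipped:
        logger.warning("clipped %d extreme propensity scores (possible separation)", n_clipped)
    scores = np.clip(scores, SCORE_CLIP, 1.0 - SCORE_CLIP)
    return PropensityFit(scores=scores, method=method, model=model)


def nearest_neighbor_match(
    fit: PropensityFit, cohort: Cohort, caliper: Optional[float] = 0.2
) -> MatchedCohorts:
    """Greedy 1:1 nearest-neighbor matching on the propensity logit.

    ``caliper=None`` disables the caliper (the random-forest convention
    here); otherwise the admissible logit distance is
    ``caliper * SD(logit)`` over all patients.
    """
    logit = fit.logit
    untreated_idx = np.flatnonzero(cohort.a == 0)
    treated_idx = np.flatnonzero(cohort.a == 1)
    if len(untreated_idx) == 0 or len(treated_idx) == 0:
        raise PSMError("both treatment arms must be nonempty")
    if len(untreated_idx) <= len(treated_idx):
        minority, majority = untreated_idx, treated_idx
    else:
        minority, majority = treated_idx, untreated_idx
    max_dist = np.inf if caliper is None else caliper * np.std(logit, ddof=1)

    order = minority[np.argsort(-logit[minority], kind="stable")]
    available = np.ones(len(majority), dtype=bool)
    maj_logit = logit[majority]
    pairs = []
    for row in order:
        if not available.any():
            break
        dists = np.abs(maj_logit - logit[row])
        dists[~available] = np.inf
        j = int(np.argmin(dists))
        if dists[j] <= max_dist:
            available[j] = False
            pairs.append((row, int(majority[j])))
    if not pairs:
        logger.warning("no pairs within caliper; matched cohorts are empty")
    rec, u_rows, t_rows = [], [], []
    for row_min, row_maj in pairs:
        row_u, row_t = (row_min, row_maj) if cohort.a[row_min] == 0 else (row_maj, row_min)
        u_rows.append(row_u)
        t_rows.append(row_t)
        rec.append(
            {
                "stratum": 0,
                "formulation": "psm",
                "untreated_id": cohort.ids[row_u],
                "treated_id": cohort.ids[row_t],
                "distance": abs(logit[row_u] - logit[row_t]),
            }
        )
    provenance = pd.DataFrame(
        rec, columns=["stratum", "formulation", "untreated_id", "treated_id", "distance"]
    )
    return MatchedCohorts(
        untreated=cohort.take(u_rows), treated=cohort.take(t_rows), provenance=provenance
    )
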