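"""Optimism-corrected (Efron/Harrell) bootstrap validation.

For each of B resamples of the training rows (with replacement, same
size) the model-fitting recipe is refit; each metric is computed on the
bootstrap sample (train performance) and on the original sample (test
performance), and their mean difference estimates the optimism. The
bias-corrected value is the apparent (training-data) value minus the
expected optimism. Resampling covers the model fit only: matched or
oversampled cohorts are resampled as the row multisets they are, without
re-running the matching stage (an option re-runs any caller-supplied
pipeline per resample for sensitivity analysis, via the recipe itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .cohort import Cohort

logger = logging.getLogger(__name__)

MAX_REDRAWS = 10


class BootstrapError(RuntimeError):
    pass


@dataclass
class ValidationReport:
    """Apparent / optimism / corrected values of one metric."""

    metric: str
    apparent: float
    optimism: float
    corrected: float
    resample_train: np.ndarray
    resample_test: np.ndarray
    ci_lower: float
    ci_upper: float
    B: int
    seed: int


def validate(
    recipe: Callable[[Cohort], object],
    cohort: Cohort,
    metrics: Mapping[str, Callable[[object, Cohort], float]],
    B: int = 100,
    seed: int = 0,
) -> dict:
    """Bias-corrected bootstrap of (recipe, metric) pairs.

    ``recipe`` maps a cohort (row multiset) to a fitted model; each metric
    maps (fit, cohort) to a scalar. Returns ``{name: ValidationReport}``.
    Resamples without events are redrawn (at most 10 times each). The
    calibration slope follows its usual convention: the train-side value
    is identically 1 by maximum-likelihood self-consistency, so the
    corrected slope is the mean of the bootstrap models' slopes on the
    original data.
    """
    rng = np.random.default_rng(seed)
    apparent_fit = recipe(cohort)
    apparent = {
        name: (1.0 if name == "calibration_slope" else fn(apparent_fit, cohort))
        for name, fn in metrics.items()
    }
    train_vals = {name: np.empty(B) for name in metrics}
    test_vals = {name: np.empty(B) for name in metrics}
    n = cohort.n
    for b in range(B):
        fit_b = boot = None
        for attempt in range(MAX_REDRAWS + 1):
            idx = rng.integers(0, n, size=n)
            boot = cohort.take(idx)
            if boot.y.sum() == 0:
                logger.warning("resample %d has no events; redrawing", b)
                continue
            try:
                fit_b = recipe(boot)
                break
            except Exception as exc:  # degenerate resample (e.g. constant column)
                logger.warning("resample %d refit failed (%s); redrawing", b, exc)
        if fit_b is None:
            raise BootstrapError(
                f"resample {b} kept failing after {MAX_REDRAWS + 1} draws"
            )
        for name, fn in metrics.items():
            train_vals[name][b] = (
                1.0 if name == "calibration_slope" else fn(fit_b, boot)
            )
            test_vals[name][b] = fn(fit_b, cohort)
    reports = {}
    for name in metrics:
        optimism = float(np.mean(train_vals[name] - test_vals[name]))
        lo, hi = np.percentile(test_vals[name], [2.5, 97.5])
        reports[name] = ValidationReport(
            metric=name,
            apparent=float(apparent[name]),
            optimism=optimism,
            corrected=float(apparent[name]) - optimism,
            resample_train=train_vals[name],
            resample_test=test_vals[name],
            ci_lower=float(lo),
            ci_upper=float(hi),
            B=B,
            seed=seed,
        )
    return reports
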