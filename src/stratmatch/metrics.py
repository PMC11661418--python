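"""Discrimination and calibration metrics for horizon-risk survival models.

Discrimination: Harrell's concordance (pairs usable iff the shorter time
is an event; tied risks count 1/2) and Uno's IPCW concordance truncated
at the horizon (weights 1/G(t)^2 from the censoring Kaplan-Meier).
Overall: the Graf/IPCW Brier score at the horizon. Calibration: the OE
ratio (observed over mean predicted risk), the calibration slope (Cox
coefficient of the model's own linear predictor on evaluation data), and
smoothed-calibration summaries ICI/E50/E90/Emax built from a flexible
recalibration of the event on restricted cubic splines of
cloglog(predicted risk).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index
from sksurv.metrics import concordance_index_ipcw
from sksurv.util import Surv

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    pass


@dataclass
class CalibrationReport:
    """Absolute-difference summaries of smoothed observed vs predicted risk."""

    oe: float
    ici: float
    e50: float
    e90: float
    emax: float
    slope: float


def km_estimator(t, y) -> Callable[[np.ndarray], np.ndarray]:
    """Product-limit survival estimate; returns a right-continuous step function."""
    t, y = np.asarray(t, dtype=float), np.asarray(y)
    if len(t) == 0:
        raise MetricError("empty sample")
    kmf = KaplanMeierFitter().fit(t, y)
    times = kmf.survival_function_.index.to_numpy()
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()

    def S(q):
        q = np.asarray(q, dtype=float)
        idx = np.searchsorted(times, q, side="right") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)
        return out if out.ndim else float(out)

    return S


def censoring_km(t, y) -> Callable[[np.ndarray], np.ndarray]:
    """Kaplan-Meier of the censoring distribution (censorings as events)."""
    return km_estimator(t, 1 - np.asarray(y))


def harrell_c(t, y, risk_scores) -> float:
    """Harrell's concordance of predicted risks against censored outcomes."""
    t, y, risk = map(np.asarray, (t, y, risk_scores))
    if len(t) < 2:
        raise MetricError("need at least two subjects")
    if y.sum() == 0:
        raise MetricError("no events: concordance undefined")
    # higher risk should mean shorter survival, so negate for lifelines
    return float(concordance_index(t, -risk, y))


def uno_c(t, y, risk_scores, tau: float) -> float:
    """Uno's IPCW concordance truncated at ``tau``.

    When the censoring Kaplan-Meier hits zero before ``tau`` the
    truncation time is pulled back to the last supported time, with a
    warning.
    """
    t, y, risk = map(np.asarray, (t, y, risk_scores))
    G = censoring_km(t, y)
    if G(tau) <= 0:
        positive = t[(G(t) > 0)]
        new_tau = float(positive.max()) if len(positive) else float(t.min())
        logger.warning(
            "censoring survival is 0 before tau=%.2f; truncating at %.2f", tau, new_tau
        )
        tau = new_tau
    s = Surv.from_arrays(y.astype(bool), t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c, *_ = concordance_index_ipcw(s, s, risk, tau=tau)
    return float(c)


def brier_score(t, y, risk, horizon: float) -> float:
    """Graf's IPCW Brier score of horizon-risk predictions.

    Events before the horizon are weighted by 1/G(t_i-), survivors past it
    by 1/G(horizon), subjects censored before the horizon contribute 0.
    """
    t, y, risk = map(np.asarray, (t, y, risk))
    G = censoring_km(t, y)
    g_h = G(horizon)
    if g_h <= 0:
        raise MetricError("censoring survival is 0 at the horizon; Brier undefined")
    surv_prob = 1.0 - risk
    event_before = (t <= horizon) & (y == 1)
    after = t > horizon
    # left limit G(t-): evaluate just below the subject's own time
    g_left = G(np.maximum(t - 1e-9, 0.0))
    w = np.zeros(len(t))
    w[event_before] = 1.0 / g_left[event_before]
    w[after] = 1.0 / g_h
    sq = np.where(after, (surv_prob - 1.0) ** 2, surv_prob**2)
    return float(np.mean(w * sq))


def oe_ratio(t, y, risk, horizon: float) -> float:
    """Observed (1 - KM at horizon) over mean predicted risk."""
    risk = np.asarray(risk, dtype=float)
    predicted = risk.mean()
    if predicted <= 0:
        raise MetricError("mean predicted risk is 0; OE undefined")
    observed = 1.0 - km_estimator(t, y)(horizon)
    return float(observed / predicted)


def _rcs_basis(x: np.ndarray, n_knots: int = 3) -> np.ndarray:
    """Restricted (natural) cubic spline truncated-power basis.

    Knots at equally spaced percentiles between the 10th and 90th;
    ``n_knots`` knots yield ``n_knots - 1`` columns (linear + nonlinear).
    """
    knots = np.percentile(x, np.linspace(10, 90, n_knots))
    knots = np.unique(knots)
    if len(knots) < 3:
        return x[:, None]
    k = knots
    norm = (k[-1] - k[0]) ** 2
    cols = [x]
    pos = lambda v: np.maximum(v, 0.0) ** 3
    for j in range(len(k) - 2):
        term = (
            pos(x - k[j])
            - pos(x - k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
            + pos(x - k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2])
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


def smoothed_calibration(t, y, risk, horizon: float, n_knots: int = 3) -> np.ndarray:
    """Model-based observed event probability at the horizon per patient.

    Fits a Cox recalibration model of the outcome on a restricted cubic
    spline of cloglog(predicted risk) and evaluates each patient's
    predicted-observed probability. With a degenerate (constant) risk
    distribution the observed probability is the Kaplan-Meier estimate for
    everyone.
    """
    t, y, risk = map(lambda v: np.asarray(v, dtype=float), (t, y, risk))
    if len(t) < 50:
        logger.warning("smoothed calibration on n=%d (<50) is unstable", len(t))
    if np.ptp(risk) < 1e-8:
        return np.full(len(t), 1.0 - km_estimator(t, y)(horizon))
    clipped = np.clip(risk, 1e-10, 1 - 1e-10)
    x = np.log(-np.log(1.0 - clipped))  # cloglog of event probability
    basis = _rcs_basis(x, n_knots)
    df = pd.DataFrame(basis, columns=[f"s{j}" for j in range(basis.shape[1])])
    df["_t"], df["_y"] = t, y
    for pen in (0.0, 1e-4, 1e-2):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter(penalizer=pen).fit(df, "_t", "_y")
            break
        except ConvergenceError:
            logger.warning("recalibration fit retry with penalizer %g", pen)
    else:
        raise MetricError("smoothed calibration model did not converge")
    surv = cph.predict_survival_function(df.drop(columns=["_t", "_y"]), times=[horizon])
    return 1.0 - surv.iloc[0].to_numpy(dtype=float)


def calibration_errors(observed, risk) -> tuple:
    """(ICI, E50, E90, Emax): mean/median/90th-percentile/max |observed - predicted|."""
    observed, risk = np.asarray(observed), np.asarray(risk)
    if len(observed) == 0 or len(observed) != len(risk):
        raise MetricError("observed and predicted must be equal-length and nonempty")
    diffs = np.abs(observed - risk)
    return (
        float(diffs.mean()),
        float(np.median(diffs)),
        float(np.percentile(diffs, 90)),
        float(diffs.max()),
    )


def calibration_slope(fit, cohort) -> float:
    """Cox coefficient of the fitted linear predictor on evaluation data.

    1.0 on the model's own training data (maximum-likelihood
    self-consistency); < 1 signals overfitting on fresh data.
    """
    lp = fit.linear_predictor(cohort)
    if np.ptp(lp) < 1e-12:
        raise MetricError("constant linear predictor; slope undefined")
    if cohort.y.sum() == 0:
        raise MetricError("no events in evaluation sample")
    df = pd.DataFrame({"lp": lp, "_t": cohort.t, "_y": cohort.y})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph = CoxPHFitter().fit(df, "_t", "_y", fit_options={"precision": 1e-10})
    return float(cph.params_["lp"])


def evaluate_model(fit, cohort, horizon: float = 60.0) -> dict:
    """All metrics of one fitted model on one evaluation cohort."""
    risk = fit.predict_risk(cohort, horizon)
    t, y = cohort.t, cohort.y
    observed = smoothed_calibration(t, y, risk, horizon)
    ici, e50, e90, emax = calibration_errors(observed, risk)
    return {
        "harrell_c": harrell_c(t, y, risk),
        "uno_c": uno_c(t, y, risk, tau=horizon),
        "brier": brier_score(t, y, risk, horizon),
        "oe": oe_ratio(t, y, risk, horizon),
        "ici": ici,
        "e50": e50,
        "e90": e90,
        "emax": emax,
        "calibration_slope": calibration_slope(fit, cohort),
    }
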