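"""Leave-one-out predictive performance of the comparator method.

For each patient, a Passing-Bablok regression is fitted on all *other*
patients' pairs, and the held-out patient's reference (WB)
concentration is predicted from their comparator (DBS) concentration.
Prediction errors are summarised with the Sheiner-Beal median-based
statistics:

    MPE   = median(pred - obs)                      [µg/L]   (bias)
    MPPE  = median(100 (pred - obs) / obs)          [%]      (bias)
    RMSE  = sqrt(median((pred - obs)^2))            [µg/L]   (imprecision)
    MAPE  = median(100 |pred - obs| / obs)          [%]      (imprecision)

RMSE here is a root-*median*-square (for odd n it equals the median
absolute error exactly); the conventional root-mean-square is reported
alongside, clearly labelled.  The cross-validation verdict passes when
|MPPE| < 15%, MAPE < 15%, and at least 67% of patients have an absolute
percentage prediction error below 20%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import LeaveOneOut

from .passing_bablok import DegenerateDataError, PassingBablok
from .samples import AnalysisPair

__all__ = [
    "PredictionSet",
    "PredictionMetrics",
    "Verdict",
    "loo_predict",
    "prediction_metrics",
    "acceptance_verdict",
]

MPPE_LIMIT = 15.0
MAPE_LIMIT = 15.0
FRACTION_LIMIT = 67.0
WITHIN_THRESHOLD = 20.0


@dataclass(frozen=True)
class PredictionSet:
    """Per-patient leave-one-out predictions, aligned by label."""

    labels: tuple[str, ...]
    observed: np.ndarray
    predicted: np.ndarray
    loo_slope: np.ndarray
    loo_intercept: np.ndarray
    excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class Verdict:
    passed: bool
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class PredictionMetrics:
    """Sheiner-Beal summary statistics plus the cross-validation verdict."""

    mpe: float
    mppe: float
    rmse_median: float
    mape: float
    fraction_within_20pct: float
    rmse_mean: float
    n: int
    verdict: Verdict = field(default=None)  # type: ignore[assignment]


def loo_predict(pair: AnalysisPair) -> PredictionSet:
    """Leave-one-out Passing-Bablok prediction of y from x.

    Each reduced fit omits exactly one patient; CI computation is
    suppressed (only point estimates are needed).  A patient whose
    reduced fit is degenerate is excluded from the metrics with a
    warning.
    """
    if pair.n < 4:
        raise ValueError(
            f"leave-one-out prediction needs at least 4 pairs so every "
            f"reduced fit keeps 3; got {pair.n}"
        )
    X = pair.x.reshape(-1, 1)
    labels, obs, preds, slopes, intercepts, excluded = [], [], [], [], [], []
    for train, test in LeaveOneOut().split(X):
        i = int(test[0])
        try:
            est = PassingBablok(ci=None).fit(X[train], pair.y[train])
        except DegenerateDataError:
            warnings.warn(
                f"reduced fit failed for patient {pair.labels[i]}; "
                "excluded from prediction metrics",
                stacklevel=2,
            )
            excluded.append(pair.labels[i])
            continue
        labels.append(pair.labels[i])
        obs.append(pair.y[i])
        preds.append(float(est.predict(X[test])[0]))
        slopes.append(est.slope_)
        intercepts.append(est.intercept_)
    return PredictionSet(
        labels=tuple(labels),
        observed=np.array(obs),
        predicted=np.array(preds),
        loo_slope=np.array(slopes),
        loo_intercept=np.array(intercepts),
        excluded=tuple(excluded),
    )


def prediction_metrics(
    pred: PredictionSet,
    *,
    within_threshold: float = WITHIN_THRESHOLD,
) -> PredictionMetrics:
    """Sheiner-Beal bias/imprecision statistics over retained patients."""
    if len(pred.observed) < 1:
        raise ValueError("no predictions to summarise")
    err = pred.predicted - pred.observed
    pct = 100.0 * err / pred.observed
    metrics = PredictionMetrics(
        mpe=float(np.median(err)),
        mppe=float(np.median(pct)),
        rmse_median=float(np.sqrt(np.median(err**2))),
        mape=float(np.median(np.abs(pct))),
        fraction_within_20pct=float(100.0 * np.mean(np.abs(pct) < within_threshold)),
        rmse_mean=float(np.sqrt(np.mean(err**2))),
        n=len(err),
    )
    object.__setattr__(metrics, "verdict", acceptance_verdict(metrics))
    return metrics


def acceptance_verdict(
    metrics: PredictionMetrics,
    *,
    mppe_limit: float = MPPE_LIMIT,
    mape_limit: float = MAPE_LIMIT,
    fraction_limit: float = FRACTION_LIMIT,
) -> Verdict:
    """Cross-validation verdict with individually listed failures."""
    reasons = []
    if not abs(metrics.mppe) < mppe_limit:
        reasons.append(f"|MPPE| = {abs(metrics.mppe):.1f}% not < {mppe_limit:g}%")
    if not metrics.mape < mape_limit:
        reasons.append(f"MAPE = {metrics.mape:.1f}% not < {mape_limit:g}%")
    if not metrics.fraction_within_20pct >= fraction_limit:
        reasons.append(
            f"only {metrics.fraction_within_20pct:.1f}% of samples within 20% "
            f"(need >= {fraction_limit:g}%)"
        )
    return Verdict(passed=not reasons, reasons=tuple(reasons))
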