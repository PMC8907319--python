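"""Calibration/prediction error metrics: Rc, RMSEC, Rp, RMSEP, SEP, Bias.

Conventions (fixed, not user-selectable, so reports stay comparable):

* residual e_i = predicted_i - reference_i, hence Bias = mean(e);
* RMSEC/RMSEP use the 1/n denominator, SEP the bias-corrected 1/(n-1)
  denominator, which makes RMSEP^2 = SEP^2*(n-1)/n + Bias^2 an exact
  algebraic identity;
* Rc/Rp are Pearson product-moment correlations between predicted and
  measured values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .models import FittedModel, predict

__all__ = ["EvaluationReport", "rmse", "bias", "sep", "pearson_r", "evaluate"]


def _pair(y, yhat, min_n=1):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {y.size}")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean square error, sqrt(sum((yhat - y)^2) / n)."""
    y, yhat = _pair(y, yhat)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def bias(y, yhat) -> float:
    """Mean signed error, mean(yhat - y)."""
    y, yhat = _pair(y, yhat)
    return float(np.mean(yhat - y))


def sep(y, yhat) -> float:
    """Bias-corrected standard error of prediction: sd of residuals, ddof=1."""
    y, yhat = _pair(y, yhat, min_n=2)
    e = yhat - y
    return float(np.sqrt(np.sum((e - e.mean()) ** 2) / (e.size - 1)))


def pearson_r(y, yhat) -> float:
    """Product-moment correlation; raises on zero variance in either input."""
    y, yhat = _pair(y, yhat, min_n=2)
    sy = y - y.mean()
    sh = yhat - yhat.mean()
    denom = np.sqrt((sy @ sy) * (sh @ sh))
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.clip((sy @ sh) / denom, -1.0, 1.0))


@dataclass
class EvaluationReport:
    """Six-figure model report; NaN marks a metric undefined for the data."""

    component: str
    method: str
    Rc: float
    RMSEC: float
    Rp: float
    RMSEP: float
    SEP: float
    Bias: float
    n_calibration: int = 0
    n_prediction: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def to_row(self) -> dict:
        return asdict(self)

    def identity_gap(self) -> float:
        """|RMSEP^2 - (SEP^2*(n-1)/n + Bias^2)|; ~0 for any emitted report."""
        n = self.n_prediction
        return abs(self.RMSEP**2 - (self.SEP**2 * (n - 1) / n + self.Bias**2))


def evaluate(
    model: FittedModel,
    X_cal,
    y_cal,
    X_pred,
    y_pred,
    component: str = "",
    method: str = "",
) -> EvaluationReport:
    """Score a trained model on its calibration set and a held-out prediction set.

    Correlations that are undefined (e.g. a constant-prediction model) are
    reported as NaN rather than failing the whole report.
    """
    yhat_cal = predict(model, X_cal)
    yhat_pred = predict(model, X_pred)

    def _safe_r(y, yh):
        try:
            return pearson_r(y, yh)
        except ValueError:
            return math.nan

    return EvaluationReport(
        component=component,
        method=method or model.kind,
        Rc=_safe_r(y_cal, yhat_cal),
        RMSEC=rmse(y_cal, yhat_cal),
        Rp=_safe_r(y_pred, yhat_pred),
        RMSEP=rmse(y_pred, yhat_pred),
        SEP=sep(y_pred, yhat_pred),
        Bias=bias(y_pred, yhat_pred),
        n_calibration=len(np.asarray(y_cal).ravel()),
        n_prediction=len(np.asarray(y_pred).ravel()),
    )
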