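"""Regression evaluation metrics, including the composite CPE/ACC family.

Percentage metrics are returned on the 0-100 scale:

* MPE   -- maximum percentage error, max_i |x_i - y_i| / y_i * 100
* MAPE  -- mean absolute percentage error, with an epsilon guard in the
           denominator
* RMSPE -- root mean squared error divided by the *mean of the truths*
           (not per-sample), * 100
* CPE   -- (MPE + MAPE + RMSPE) / 3
* ACC   -- 100 - CPE

plus standard RMSE (in the target's units) and R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import mean_squared_error, r2_score

__all__ = [
    "MetricReport", "mpe", "mape", "rmspe", "cpe_acc", "rmse_r2", "compute_report",
]

DEFAULT_EPS = 1e-8


def _validate(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"predictions {x.shape} and truths {y.shape} must be equal-length 1-D")
    if x.size == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in metric input")
    return x, y


@dataclass(frozen=True)
class MetricReport:
    """All metrics for one parameter on one evaluation split."""

    rmse: float
    r2: float
    mpe: float
    mape: float
    rmspe: float
    cpe: float
    acc: float

    def as_dict(self) -> dict:
        return {
            "RMSE": self.rmse, "R2": self.r2, "MPE": self.mpe, "MAPE": self.mape,
            "RMSPE": self.rmspe, "CPE": self.cpe, "ACC": self.acc,
        }


def mpe(predictions, truths) -> float:
    """Maximum percentage error (worst case over subjects), in %.

    The denominator is the raw truth — a zero truth is a domain error.
    """
    x, y = _validate(predictions, truths)
    if np.any(y == 0):
        raise ZeroDivisionError("MPE is undefined for zero truths")
    return float(np.max(np.abs(x - y) / y) * 100.0)


def mape(predictions, truths, eps: float = DEFAULT_EPS) -> float:
    """Mean absolute percentage error in %, with epsilon-guarded denominator."""
    x, y = _validate(predictions, truths)
    return float(np.mean(np.abs(x - y) / np.maximum(eps, np.abs(y))) * 100.0)


def rmspe(predictions, truths) -> float:
    """Root mean square percentage error in %.

    The denominator is the mean of the truths (a single cohort-level
    scale), not a per-sample truth.
    """
    x, y = _validate(predictions, truths)
    ybar = float(np.mean(y))
    if ybar == 0:
        raise ZeroDivisionError("RMSPE is undefined when the truth mean is zero")
    return float(np.sqrt(np.mean((x - y) ** 2)) / ybar * 100.0)


def cpe_acc(mpe_pct: float, mape_pct: float, rmspe_pct: float) -> tuple[float, float]:
    """Comprehensive percentage error and accuracy rate.

    CPE is the arithmetic mean of the three component percentages;
    ACC = 100 - CPE.
    """
    for v in (mpe_pct, mape_pct, rmspe_pct):
        if v < 0:
            raise ValueError("component percentages must be non-negative")
    cpe = (mpe_pct + mape_pct + rmspe_pct) / 3.0
    return cpe, 100.0 - cpe


def rmse_r2(predictions, truths) -> tuple[float, float]:
    """Root mean squared error (target units) and coefficient of determination."""
    x, y = _validate(predictions, truths)
    if x.size < 2:
        raise ValueError("R^2 needs at least 2 samples")
    if np.var(y) == 0:
        raise ZeroDivisionError("R^2 is undefined for zero target variance")
    return float(np.sqrt(mean_squared_error(y, x))), float(r2_score(y, x))


def compute_report(predictions, truths, eps: float = DEFAULT_EPS) -> MetricReport:
    """Full metric report for one parameter on one split."""
    m_mpe = mpe(predictions, truths)
    m_mape = mape(predictions, truths, eps)
    m_rmspe = rmspe(predictions, truths)
    cpe, acc = cpe_acc(m_mpe, m_mape, m_rmspe)
    m_rmse, m_r2 = rmse_r2(predictions, truths)
    return MetricReport(
        rmse=m_rmse, r2=m_r2, mpe=m_mpe, mape=m_mape, rmspe=m_rmspe, cpe=cpe, acc=acc
    )
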