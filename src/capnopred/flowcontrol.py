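"""Adaptive exponential-smoothing flow controller.

A capnography sampling pump must track the subject's respiratory flow.
The controller forecasts the next respiratory flow with truncated
exponential smoothing, measures the forecast error, adapts the
smoothing parameter in proportion to the ratio of the current error to
its sliding-window mean, and re-smooths the recent sampling flows with
the updated parameter to set the next pump command:

    F_hat   = sum_{j=0}^{N-1} alpha (1-alpha)^j F[i-j]
    E       = F_hat - F_actual
    E_bar   = mean of the last W errors
    alpha'  = alpha * (1 + beta * (E / E_bar - 1)),  clamped to (0.01, 0.99)
    f_next  = sum_{j=0}^{N-1} alpha' (1-alpha')^j f[i-j]

The smoothing series is truncated at the N buffered values (the
controller stores exactly N flows).  Histories are passed most-recent
first.  When |E_bar| is numerically zero the ratio is defined as 1, so
alpha is left unchanged; with beta = 0 the controller reduces to plain
fixed-parameter exponential smoothing.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FlowControllerConfig",
    "predict_next_flow",
    "forecast_error",
    "window_mean_error",
    "update_alpha",
    "control_flow",
    "run_controller",
]

ALPHA_MIN = 0.01
ALPHA_MAX = 0.99
EBAR_EPS = 1e-9


@dataclass(frozen=True)
class FlowControllerConfig:
    """Controller tuning: initial flow/alpha, window sizes, adaptation gain."""

    f0: float = 1.0          # initial sampling flow, L/min
    alpha0: float = 0.5      # initial smoothing parameter, in (0, 1)
    N: int = 5               # prediction window (number of buffered flows)
    W: int = 5               # error window
    beta: float = 0.1        # self-adjustment coefficient, >= 0

    def __post_init__(self):
        if not 0.0 < self.alpha0 < 1.0:
            raise ValueError("alpha0 must be in (0, 1)")
        if self.N < 1 or self.W < 1:
            raise ValueError("N and W must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


def _smooth(history, alpha: float, n: int) -> float:
    """Truncated exponential smoothing of a most-recent-first history."""
    h = np.asarray(list(history)[:n], dtype=float)
    weights = alpha * (1.0 - alpha) ** np.arange(h.size)
    return float(weights @ h)


def predict_next_flow(history, alpha: float) -> float:
    """Forecast the next respiratory flow from the last N actual flows.

    ``history`` is ordered most-recent first; the geometric weight
    series is truncated at the available terms.
    """
    history = list(history)
    if not history:
        raise RuntimeError("cannot predict from an empty flow history")
    return _smooth(history, alpha, len(history))


def forecast_error(predicted: float, actual: float) -> float:
    """Signed forecast error, predicted minus actual."""
    return predicted - actual


def window_mean_error(errors, w: int) -> float:
    """Mean of the last min(W, available) forecast errors."""
    errors = list(errors)
    if not errors:
        raise RuntimeError("no forecast errors recorded yet")
    recent = errors[-w:]
    return float(np.mean(recent))


def update_alpha(alpha: float, e: float, e_bar: float, beta: float) -> float:
    """Error-ratio adaptation of the smoothing parameter, clamped.

    When the window-mean error is numerically zero the ratio is taken
    as 1 (no update), avoiding the division singularity.
    """
    ratio = 1.0 if abs(e_bar) < EBAR_EPS else e / e_bar
    new = alpha * (1.0 + beta * (ratio - 1.0))
    return float(np.clip(new, ALPHA_MIN, ALPHA_MAX))


def control_flow(sample_history, alpha: float) -> float:
    """Next sampling-flow command from the recent pump flows (most-recent first)."""
    sample_history = list(sample_history)
    if not sample_history:
        raise RuntimeError("cannot control flow from an empty sampling history")
    return _smooth(sample_history, alpha, len(sample_history))


def run_controller(flow_trace, config: FlowControllerConfig) -> pd.DataFrame:
    """Replay a respiratory-flow trace through the adaptive controller.

    The first N samples prime the flow buffer; every subsequent sample
    triggers one forecast / error / adaptation / control step.  Returns
    a per-step log with columns ``step, F, F_hat, E, E_bar, alpha, f``
    of length ``len(flow_trace) - N``.
    """
    flow_trace = np.asarray(flow_trace, dtype=float)
    n_steps = flow_trace.size - config.N
    if n_steps < 1:
        raise ValueError(
            f"trace length {flow_trace.size} must exceed the prediction "
            f"window N={config.N}"
        )
    flows = deque(flow_trace[: config.N][::-1], maxlen=config.N)  # most-recent first
    samples = deque([config.f0], maxlen=config.N)
    errors = deque(maxlen=config.W)
    alpha = config.alpha0

    rows = []
    for step in range(n_steps):
        actual = float(flow_trace[config.N + step])
        f_hat = predict_next_flow(flows, alpha)
        e = forecast_error(f_hat, actual)
        errors.append(e)
        e_bar = window_mean_error(errors, config.W)
        alpha = update_alpha(alpha, e, e_bar, config.beta)
        f_next = control_flow(samples, alpha)
        rows.append(
            {"step": step, "F": actual, "F_hat": f_hat, "E": e,
             "E_bar": e_bar, "alpha": alpha, "f": f_next}
        )
        flows.appendleft(actual)
        samples.appendleft(f_next)
    return pd.DataFrame(rows)
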