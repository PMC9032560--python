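"""Improved-KNN error-correction stage.

The two first-stage regressors emit, per subject, a 4-D prediction
vector (FEV1_med, FVC_med, FEV1_seq, FVC_seq).  The corrector stores
the training quads together with the subjects' true (FEV1, FVC), and
maps a test quad to the plain arithmetic mean of the true targets of
its K nearest training quads under Euclidean (Minkowski p=2) distance.
All four coordinates share units of liters, so quads are not
standardized before the distance computation.  Ties in distance are
broken by training-set index order; there is no distance weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NotFittedError

__all__ = ["PredictionQuad", "CorrectionModel", "minkowski_distance",
           "fit_correction", "predict_corrected"]

#: Column order of the 4-D prediction space.
QUAD_FIELDS = ("fev1_med", "fvc_med", "fev1_seq", "fvc_seq")


def quad_array(fev1_med, fvc_med, fev1_seq, fvc_seq) -> np.ndarray:
    return np.array([fev1_med, fvc_med, fev1_seq, fvc_seq], dtype=float)


# Alias kept for readers thinking in terms of the 4-vector.
PredictionQuad = quad_array


def minkowski_distance(x, y, p: float = 2.0) -> float:
    """Minkowski distance (sum |x_i - y_i|^p)^(1/p); p=2 is Euclidean."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if p < 1:
        raise ValueError("Minkowski order p must be >= 1")
    return float(np.sum(np.abs(x - y) ** p) ** (1.0 / p))


@dataclass
class CorrectionModel:
    """Stored training quads/truths plus the neighbor count K."""

    train_quads: np.ndarray    # (n, 4)
    train_truths: np.ndarray   # (n, 2): true (FEV1, FVC)
    k: int = 5
    p: float = 2.0


def fit_correction(train_quads, train_truths, k: int = 5, p: float = 2.0) -> CorrectionModel:
    """Store the training predictions and truths (no learning beyond storage)."""
    quads = np.asarray(train_quads, dtype=float)
    truths = np.asarray(train_truths, dtype=float)
    if quads.ndim != 2 or quads.shape[1] != 4:
        raise ValueError(f"train quads must be (n, 4), got {quads.shape}")
    if truths.ndim != 2 or truths.shape[1] != 2:
        raise ValueError(f"train truths must be (n, 2), got {truths.shape}")
    if quads.shape[0] != truths.shape[0]:
        raise ValueError(
            f"quad count {quads.shape[0]} != truth count {truths.shape[0]}"
        )
    if not 1 <= k <= quads.shape[0]:
        raise ValueError(f"K={k} must be in [1, {quads.shape[0]}]")
    if p < 1:
        raise ValueError("Minkowski order p must be >= 1")
    return CorrectionModel(train_quads=quads, train_truths=truths, k=k, p=p)


def predict_corrected(model: CorrectionModel, test_quads) -> np.ndarray:
    """Corrected (FEV1, FVC) for each test quad.

    For each test quad: distances to every stored training quad, the K
    smallest selected with stable index-order tie-breaking, and the mean
    of those neighbors' true targets returned.  Accepts a single quad
    (shape (4,)) or a batch (n, 4); returns matching (2,) or (n, 2).
    """
    if model is None or model.train_quads is None:
        raise NotFittedError("correction model is not fitted")
    quads = np.atleast_2d(np.asarray(test_quads, dtype=float))
    if quads.shape[1] != 4:
        raise ValueError(f"test quads must have 4 columns, got {quads.shape}")
    diffs = np.abs(quads[:, None, :] - model.train_quads[None, :, :])
    dists = np.sum(diffs ** model.p, axis=2)          # monotone in true distance
    order = np.argsort(dists, axis=1, kind="stable")  # stable -> index tie-break
    neighbors = order[:, : model.k]
    preds = model.train_truths[neighbors].mean(axis=1)
    if np.asarray(test_quads).ndim == 1:
        return preds[0]
    return preds
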