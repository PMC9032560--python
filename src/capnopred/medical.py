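"""Two-level medical-feature regression structure.

Level 1 is a binary airflow-limitation classifier: an RBF-kernel
support-vector machine trained on the standardized 15-dimensional
medical feature vector (5 demographic fields + 10 capnogram features)
with the GOLD fixed-ratio label FEV1/FVC < 0.7 (strict).  Its raw
decision margin z is squashed through a sigmoid, 1 / (1 + e^-z) — the
plain logistic of the margin, not Platt scaling with fitted slope — to
give an obstruction probability.

Level 2 appends that probability to the original features (16-D) and
fits one gradient-boosted regression-tree ensemble (XGBoost) per target
(FEV1, FVC), with hyperparameters chosen by a coarse-to-fine heuristic
search scored by inner 3-fold cross-validated RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBRegressor

from .errors import NotFittedError

__all__ = [
    "MEDICAL_FEATURE_ORDER",
    "StageOneModel", "StageTwoModel",
    "label_obstruction", "medical_feature_matrix",
    "train_stage1", "obstruction_probability", "fuse_features",
    "heuristic_search", "train_stage2", "predict_medical",
    "feature_importances",
]

#: Fixed, documented feature order of the 15-D medical vector.
MEDICAL_FEATURE_ORDER = (
    "male", "age_y", "height_cm", "weight_kg", "bmi",
    "C12", "C23", "V12", "V23", "V2", "V3", "S2", "S3", "S3_over_S2", "Angle23",
)

PREDICTION_FLOOR = 0.1  # L

#: Default coarse grid for the stage-2 heuristic search.
DEFAULT_STAGE2_GRID = (
    {"n_estimators": 150, "max_depth": 3, "learning_rate": 0.1},
    {"n_estimators": 300, "max_depth": 3, "learning_rate": 0.05},
    {"n_estimators": 150, "max_depth": 5, "learning_rate": 0.1},
    {"n_estimators": 300, "max_depth": 5, "learning_rate": 0.05},
)


def label_obstruction(fev1, fvc):
    """GOLD fixed-ratio airflow-limitation label: FEV1/FVC < 0.7, strict.

    Accepts scalars or arrays; FVC must be positive.
    """
    fev1 = np.asarray(fev1, dtype=float)
    fvc = np.asarray(fvc, dtype=float)
    if np.any(fvc <= 0):
        raise ValueError("FVC must be positive")
    out = fev1 / fvc < 0.7
    return bool(out) if out.ndim == 0 else out


def medical_feature_matrix(records) -> np.ndarray:
    """(n, 15) feature matrix from subject records, in MEDICAL_FEATURE_ORDER."""
    rows = []
    for r in records:
        rows.append(
            [r.male, r.age, r.height, r.weight, r.bmi, *r.features.as_array()]
        )
    x = np.asarray(rows, dtype=float)
    _check_features(x)
    return x


def _check_features(x: np.ndarray, dim: int = 15) -> None:
    if x.ndim != 2 or x.shape[1] != dim:
        raise ValueError(f"expected (n, {dim}) feature matrix, got {x.shape}")
    if not np.all(np.isfinite(x)):
        bad = np.argwhere(~np.isfinite(x))
        raise ValueError(f"non-finite feature values at positions {bad[:5].tolist()}")


@dataclass
class StageOneModel:
    """Fitted margin classifier + the standardization learned on training data."""

    svc: SVC
    scaler: StandardScaler

    def decision_score(self, features: np.ndarray) -> np.ndarray:
        _check_features(np.asarray(features, dtype=float))
        return self.svc.decision_function(self.scaler.transform(features))


def train_stage1(
    features, labels, c_grid=(0.1, 1.0, 10.0), gamma_factors=(0.5, 1.0, 2.0),
    seed: int = 0,
) -> StageOneModel:
    """Fit the airflow-limitation classifier.

    Standardizes features (statistics learned here, i.e. on the training
    fold only), then selects C and the RBF width by 3-fold accuracy over
    a small grid around the 'scale' gamma heuristic.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_features(x)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("stage-1 training requires both obstruction classes")

    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    gamma_scale = 1.0 / (x.shape[1] * xs.var())

    best = None
    n_splits = min(3, np.min(np.bincount(y)))
    for c in c_grid:
        for gf in gamma_factors:
            gamma = gamma_scale * gf
            if n_splits >= 2:
                kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
                accs = []
                for tr, va in kf.split(xs):
                    if len(np.unique(y[tr])) < 2:
                        continue
                    m = SVC(kernel="rbf", C=c, gamma=gamma).fit(xs[tr], y[tr])
                    accs.append(np.mean(m.predict(xs[va]) == y[va]))
                score = np.mean(accs) if accs else -np.inf
            else:
                score = -np.inf
            if best is None or score > best[0]:
                best = (score, c, gamma)
    _, c, gamma = best
    svc = SVC(kernel="rbf", C=c, gamma=gamma).fit(xs, y)
    return StageOneModel(svc=svc, scaler=scaler)


def obstruction_probability(model: StageOneModel, features) -> np.ndarray:
    """Sigmoid of the raw decision margin: p = 1 / (1 + e^-z), in (0, 1)."""
    z = model.decision_score(np.asarray(features, dtype=float))
    return 1.0 / (1.0 + np.exp(-z))


def fuse_features(features, p) -> np.ndarray:
    """Append the obstruction probability as the 16th feature column."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if p.shape[0] != x.shape[0]:
        raise ValueError("probability count must match the number of rows")
    return np.hstack([x, p[:, None]])


def _make_booster(params: dict, seed: int) -> XGBRegressor:
    defaults = dict(
        n_estimators=300, max_depth=3, learning_rate=0.05,
        colsample_bytree=0.8, reg_lambda=1.0, gamma=0.0,
        subsample=1.0, tree_method="hist", n_jobs=1, random_state=seed,
    )
    defaults.update(params)
    return XGBRegressor(**defaults)


def heuristic_search(
    grid, x, y, folds: int = 3, seed: int = 0
) -> dict:
    """Coarse-to-fine hyperparameter search scored by inner-CV RMSE.

    Evaluates every point of ``grid`` by ``folds``-fold cross-validated
    RMSE, then refines once around the best point (halving/doubling the
    tree count and stepping the depth by one).  Ties are broken by
    smaller n_estimators, then smaller max_depth.  Deterministic for a
    fixed seed.
    """
    grid = [dict(g) for g in grid]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def cv_rmse(params: dict) -> float:
        n_splits = min(folds, x.shape[0])
        if n_splits < 2:
            model = _make_booster(params, seed).fit(x, y)
            return float(np.sqrt(np.mean((model.predict(x) - y) ** 2)))
        kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
        errs = []
        for tr, va in kf.split(x):
            model = _make_booster(params, seed).fit(x[tr], y[tr])
            errs.append(np.mean((model.predict(x[va]) - y[va]) ** 2))
        return float(np.sqrt(np.mean(errs)))

    def key(item):
        score, params = item
        return (score, params.get("n_estimators", 0), params.get("max_depth", 0))

    scored = sorted(((cv_rmse(g), g) for g in grid), key=key)
    best_score, best = scored[0]
    if len(grid) == 1:
        return best

    refined = []
    for ne in {max(25, best.get("n_estimators", 300) // 2),
               best.get("n_estimators", 300) * 2}:
        for dd in (-1, 1):
            cand = dict(best)
            cand["n_estimators"] = ne
            cand["max_depth"] = max(2, best.get("max_depth", 3) + dd)
            refined.append(cand)
    scored += [(cv_rmse(g), g) for g in refined]
    return sorted(scored, key=key)[0][1]


@dataclass
class StageTwoModel:
    """Per-target gradient-boosted ensembles on the fused 16-D features."""

    booster_fev1: XGBRegressor
    booster_fvc: XGBRegressor
    params: dict = field(default_factory=dict)


def train_stage2(
    fused_features, fev1, fvc, grid=DEFAULT_STAGE2_GRID, search_folds: int = 3,
    seed: int = 0,
) -> StageTwoModel:
    """Fit the stage-2 boosted ensembles (one per target) on fused features."""
    x = np.asarray(fused_features, dtype=float)
    _check_features(x, dim=16)
    if x.shape[0] < 10:
        raise ValueError(f"stage-2 training needs n >= 10, got {x.shape[0]}")
    fev1 = np.asarray(fev1, dtype=float)
    fvc = np.asarray(fvc, dtype=float)
    params = heuristic_search(grid, x, fvc, folds=search_folds, seed=seed)
    b1 = _make_booster(params, seed).fit(x, fev1)
    b2 = _make_booster(params, seed).fit(x, fvc)
    return StageTwoModel(booster_fev1=b1, booster_fvc=b2, params=params)


def predict_medical(
    stage1: StageOneModel, stage2: StageTwoModel, features
) -> np.ndarray:
    """Full pipeline: classify -> probabilize -> fuse -> boost; (n, 2) output.

    Columns are (FEV1, FVC) in liters, floored at 0.1 L.
    """
    if stage1 is None or stage2 is None:
        raise NotFittedError("both stages must be trained before prediction")
    x = np.asarray(features, dtype=float)
    _check_features(x)
    p = obstruction_probability(stage1, x)
    fused = fuse_features(x, np.clip(p, 1e-12, 1 - 1e-12))
    pred = np.column_stack(
        [stage2.booster_fev1.predict(fused), stage2.booster_fvc.predict(fused)]
    )
    return np.maximum(pred.astype(float), PREDICTION_FLOOR)


def feature_importances(stage2: StageTwoModel) -> pd.DataFrame:
    """Gain-based importances over all 16 fused features, normalized to sum 1."""
    names = list(MEDICAL_FEATURE_ORDER) + ["p_obstruction"]
    out = {}
    for target, booster in (("fev1", stage2.booster_fev1), ("fvc", stage2.booster_fvc)):
        imp = np.asarray(booster.feature_importances_, dtype=float)
        total = imp.sum()
        out[target] = imp / total if total > 0 else np.full(len(names), 1 / len(names))
    return pd.DataFrame(out, index=names)
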