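"""Repeated stratified k-fold cross-validation harness.

The cohort is split into k (default 10) equally-sized, mutually
exclusive folds, stratified on the airflow-obstruction label so every
fold preserves the cohort's class mix; each fold serves once as the
test set, and per-fold metrics are averaged.  The whole procedure is
repeated (default 10 times) with fresh shuffles, and fold-averaged
metrics are averaged again over repeats.

``run_cv`` accepts any pipeline factory producing objects with
``fit(records)`` and ``predict(records) -> {variant: (n, 2) array}``,
so the harness can be exercised with stub pipelines as well as with the
real :class:`~capnopred.pipeline.CombinationPipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .medical import label_obstruction
from .metrics import compute_report
from .pipeline import CombinationPipeline, PipelineConfig

__all__ = ["CVPlan", "make_folds", "run_cv", "format_report"]

PARAMETERS = ("FEV1", "FVC")

#: Display names per pipeline variant, in report order.
VARIANT_LABELS = {
    "medical": "SVM+XGBoost",
    "sequence": "1D-CNN",
    "combination": "Combination",
}


@dataclass(frozen=True)
class CVPlan:
    """k folds x repeats, with stratification on the obstruction label."""

    k: int = 10
    repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.k < 2 or self.repeats < 1:
            raise ValueError("need k >= 2 folds and >= 1 repeat")


def make_folds(labels, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold assignments: list of (train_idx, test_idx) pairs.

    Folds are disjoint, cover every subject, and differ in size by at
    most one; the per-fold class fraction tracks the global fraction.
    """
    labels = np.asarray(labels).astype(int)
    if labels.size < k:
        raise ValueError(f"cannot make {k} folds from {labels.size} subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(labels.size), labels)]


def _default_factory(config: PipelineConfig):
    def factory(seed: int):
        return CombinationPipeline(config.reseeded(seed))
    return factory


def run_cv(
    records,
    plan: CVPlan = CVPlan(),
    pipeline_config: PipelineConfig | None = None,
    pipeline_factory=None,
) -> pd.DataFrame:
    """Run the repeated stratified CV experiment and aggregate metrics.

    For each repeat and fold, a fresh pipeline is fitted on the training
    folds and evaluated on the test fold; metrics are averaged over
    folds, then over repeats.  Returns a tidy frame with one row per
    (parameter, algorithm) and columns RMSE, R2, MPE, MAPE, RMSPE, CPE,
    ACC.
    """
    records = list(records)
    if len(records) < 20:
        raise ValueError(f"cohort too small for cross-validation ({len(records)})")
    if pipeline_factory is None:
        pipeline_factory = _default_factory(pipeline_config or PipelineConfig())
    labels = np.array(
        [label_obstruction(r.fev1, r.fvc) for r in records], dtype=int
    )
    truths = np.array([[r.fev1, r.fvc] for r in records], dtype=float)

    accum: dict[tuple[str, str], list[dict]] = {}
    for repeat in range(plan.repeats):
        repeat_seed = plan.seed + repeat
        folds = make_folds(labels, plan.k, seed=repeat_seed)
        fold_metrics: dict[tuple[str, str], list[dict]] = {}
        for fold_i, (tr, te) in enumerate(folds):
            pipeline = pipeline_factory(repeat_seed * 1000 + fold_i)
            pipeline.fit([records[i] for i in tr])
            preds = pipeline.predict([records[i] for i in te])
            for variant, pred in preds.items():
                pred = np.asarray(pred, dtype=float)
                for j, param in enumerate(PARAMETERS):
                    report = compute_report(pred[:, j], truths[te, j])
                    fold_metrics.setdefault((param, variant), []).append(
                        report.as_dict()
                    )
        for key, reports in fold_metrics.items():
            df = pd.DataFrame(reports)
            accum.setdefault(key, []).append(df.mean().to_dict())

    rows = []
    for (param, variant), repeat_means in accum.items():
        mean = pd.DataFrame(repeat_means).mean()
        rows.append(
            {"parameter": param,
             "algorithm": VARIANT_LABELS.get(variant, variant),
             **mean.to_dict()}
        )
    order = {label: i for i, label in enumerate(VARIANT_LABELS.values())}
    df = pd.DataFrame(rows)
    df["_order"] = df["algorithm"].map(lambda a: order.get(a, 99))
    df = df.sort_values(["parameter", "_order"]).drop(columns="_order")
    return df.reset_index(drop=True)


def format_report(report: pd.DataFrame) -> str:
    """Plain-text table of a run_cv report (RMSE in L, percentages in %)."""
    lines = [
        f"{'Parameter':<10}{'Algorithm':<14}{'RMSE':>7}{'R2':>7}"
        f"{'MPE':>8}{'MAPE':>8}{'RMSPE':>8}{'ACC':>8}"
    ]
    for _, row in report.iterrows():
        lines.append(
            f"{row['parameter']:<10}{row['algorithm']:<14}"
            f"{row['RMSE']:>7.2f}{row['R2']:>7.2f}{row['MPE']:>8.2f}"
            f"{row['MAPE']:>8.2f}{row['RMSPE']:>8.2f}{row['ACC']:>8.2f}"
        )
    return "\n".join(lines)
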