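"""End-to-end combination pipeline.

Ties the three stages together for a training cohort:

1. medical structure — SVM obstruction classifier -> sigmoid
   probability -> feature fusion -> per-target XGBoost regression;
2. sequence structure — the 1-D CNN on preprocessed CO2 sequences;
3. error correction — improved KNN over the 4-D space of the two
   structures' (FEV1, FVC) outputs.

The KNN stage must be trained on prediction quads that are honest
proxies for test-time quads, so the quads for training subjects come
from out-of-fold predictions of the two structures under an inner
stratified k-fold split (never from models that saw the subject).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import medical
from .knn import fit_correction, predict_corrected
from .medical import medical_feature_matrix, label_obstruction
from .seqnet import NetworkConfig, build_network, preprocess_sequence, \
    predict_sequence, train_network

__all__ = ["PipelineConfig", "CombinationPipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Hyperparameters of the full combination pipeline."""

    network: NetworkConfig = NetworkConfig()
    stage2_grid: tuple = medical.DEFAULT_STAGE2_GRID
    stage1_c_grid: tuple = (0.1, 1.0, 10.0)
    stage1_gamma_factors: tuple = (0.5, 1.0, 2.0)
    search_folds: int = 3
    knn_k: int = 5
    inner_folds: int = 5     # out-of-fold quad protocol for the KNN stage
    seed: int = 0

    def reseeded(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, network=replace(self.network, seed=seed))


class CombinationPipeline:
    """Fit/predict interface over the three-stage combination algorithm."""

    def __init__(self, config: PipelineConfig = PipelineConfig()):
        self.config = config
        self.stage1 = None
        self.stage2 = None
        self.network = None
        self.corrector = None

    # -- internals ---------------------------------------------------------

    def _design(self, records):
        x_med = medical_feature_matrix(records)
        seqs = np.stack(
            [preprocess_sequence(r.sequence, self.config.network.input_length)
             for r in records]
        )
        targets = np.array([[r.fev1, r.fvc] for r in records], dtype=float)
        return x_med, seqs, targets

    def _fit_structures(self, x_med, seqs, targets, seed):
        labels = label_obstruction(targets[:, 0], targets[:, 1])
        stage1 = medical.train_stage1(
            x_med, labels, c_grid=self.config.stage1_c_grid,
            gamma_factors=self.config.stage1_gamma_factors, seed=seed,
        )
        p = medical.obstruction_probability(stage1, x_med)
        fused = medical.fuse_features(x_med, np.clip(p, 1e-12, 1 - 1e-12))
        stage2 = medical.train_stage2(
            fused, targets[:, 0], targets[:, 1], grid=self.config.stage2_grid,
            search_folds=self.config.search_folds, seed=seed,
        )
        net = build_network(replace(self.config.network, seed=seed))
        train_network(net, seqs, targets)
        return stage1, stage2, net

    # -- public API --------------------------------------------------------

    def fit(self, records) -> "CombinationPipeline":
        cfg = self.config
        x_med, seqs, targets = self._design(records)
        labels = label_obstruction(targets[:, 0], targets[:, 1]).astype(int)

        # final structures on the full training set
        self.stage1, self.stage2, self.network = self._fit_structures(
            x_med, seqs, targets, cfg.seed
        )

        # out-of-fold quads for the KNN corrector
        n = len(records)
        quads = np.full((n, 4), np.nan)
        inner = min(cfg.inner_folds, int(np.min(np.bincount(labels))))
        if inner >= 2:
            skf = StratifiedKFold(n_splits=inner, shuffle=True, random_state=cfg.seed)
            for j, (tr, va) in enumerate(skf.split(x_med, labels)):
                s1, s2, net = self._fit_structures(
                    x_med[tr], seqs[tr], targets[tr], cfg.seed + 101 + j
                )
                med = medical.predict_medical(s1, s2, x_med[va])
                seq = predict_sequence(net, seqs[va])
                quads[va] = np.hstack([med, seq])
        else:
            # degenerate cohort: fall back to in-sample quads
            med = medical.predict_medical(self.stage1, self.stage2, x_med)
            seq = predict_sequence(self.network, seqs)
            quads = np.hstack([med, seq])

        k = min(cfg.knn_k, n)
        self.corrector = fit_correction(quads, targets, k=k)
        return self

    def predict(self, records) -> dict[str, np.ndarray]:
        """Per-variant (n, 2) predictions of (FEV1, FVC) in liters.

        Keys: ``medical`` (SVM+XGBoost), ``sequence`` (1D-CNN) and
        ``combination`` (KNN-corrected).
        """
        if self.corrector is None:
            raise RuntimeError("pipeline is not fitted")
        x_med, seqs, _ = self._design(records)
        med = medical.predict_medical(self.stage1, self.stage2, x_med)
        seq = predict_sequence(self.network, seqs)
        comb = predict_corrected(self.corrector, np.hstack([med, seq]))
        return {"medical": med, "sequence": seq, "combination": comb}
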