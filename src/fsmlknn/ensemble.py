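"""Weighted-scoring ensemble of per-feature FS-MLKNN base predictors.

Each drug feature type (substructures, targets, enzymes, ...) yields its own
FS-MLKNN base predictor.  The ensemble score is the linear combination
sum_i w_i S_i of the base score matrices, with nonnegative weights summing
to 1.  Weights are tuned by a genetic algorithm over the probability
simplex whose fitness is the merged AUPR of the weighted sum of
out-of-fold base scores under an internal 5-fold cross-validation of the
training drugs: bases are re-fitted on each internal fold's training
portion (restricted to the dimensions already chosen for that feature), so
overfit base predictors are not rewarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasets import DatasetBundle, FeatureTable
from .errors import ValidationError
from .ga import GAConfig, ga_maximize
from .metrics import micro_aupr_arrays
from .mlknn import MLKNNConfig, ScoreMatrix, fit_mlknn, predict_scores
from .selection import FSMLKNNModel, fit_fs_mlknn, internal_folds, predict_fs_mlknn

logger = logging.getLogger(__name__)

__all__ = ["EnsembleModel", "weighted_score", "fit_ensemble", "predict_ensemble"]


@dataclass
class EnsembleModel:
    base_models: dict[str, FSMLKNNModel]
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.base_models:
            raise ValidationError("ensemble needs at least one base model")
        if set(self.base_models) != set(self.weights):
            raise ValidationError("weights and base models must cover the same feature types")
        w = np.array([self.weights[k] for k in self.base_models])
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("weights must be nonnegative and sum to 1")


def weighted_score(weights: np.ndarray, base_scores: list[ScoreMatrix]) -> ScoreMatrix:
    """Elementwise linear combination sum_i w_i S_i of base score matrices."""
    if len(weights) != len(base_scores):
        raise ValidationError("one weight per base score matrix required")
    ref = base_scores[0]
    for sm in base_scores[1:]:
        if sm.scores.shape != ref.scores.shape or sm.drug_ids != ref.drug_ids or sm.label_ids != ref.label_ids:
            raise ValidationError("base score matrices must share shape and id order")
    stacked = np.stack([sm.scores for sm in base_scores])  # (m, n, q)
    combined = np.tensordot(np.asarray(weights, dtype=float), stacked, axes=1)
    return ScoreMatrix(list(ref.drug_ids), list(ref.label_ids), combined)


def _oof_base_scores(
    feature: FeatureTable,
    labels,
    chosen_dims: list[str],
    mlknn: MLKNNConfig,
    folds: np.ndarray,
) -> np.ndarray:
    """Out-of-fold MLKNN scores on the training drugs, restricted to chosen dims."""
    restricted = feature.restrict_dims(chosen_dims)
    n, q = labels.values.shape
    oof = np.zeros((n, q))
    for f in np.unique(folds):
        tr_ids = [d for d, m in zip(feature.drug_ids, folds != f) if m]
        te_ids = [d for d, m in zip(feature.drug_ids, folds == f) if m]
        model = fit_mlknn(restricted.restrict_drugs(tr_ids), labels.restrict_drugs(tr_ids), mlknn)
        sm = predict_scores(model, restricted.restrict_drugs(te_ids))
        oof[folds == f] = sm.scores
    return oof


def fit_ensemble(
    bundle: DatasetBundle,
    sigma: float = 0.001,
    fs_ga: GAConfig = GAConfig(),
    weight_ga: GAConfig = GAConfig(),
    mlknn: MLKNNConfig = MLKNNConfig(),
    seed: int | None = None,
) -> EnsembleModel:
    """Fit one FS-MLKNN per feature type, then GA-tune the combination weights.

    With a single feature type the weight is 1 and no GA runs.
    """
    rng = np.random.default_rng(seed)
    names = list(bundle.features)
    base_models = {
        name: fit_fs_mlknn(
            bundle.features[name], bundle.labels, sigma, fs_ga, mlknn, seed=int(rng.integers(2**31))
        )
        for name in names
    }
    if len(names) == 1:
        return EnsembleModel(base_models, {names[0]: 1.0})

    folds = internal_folds(bundle.labels.n_drugs, 5, rng)
    oof = np.stack(
        [
            _oof_base_scores(bundle.features[name], bundle.labels, base_models[name].chosen_dims, mlknn, folds)
            for name in names
        ]
    )  # (m, n, q)
    Y = bundle.labels.values

    def fitness(w: np.ndarray) -> float:
        return micro_aupr_arrays(np.tensordot(w, oof, axes=1), Y)

    ga_cfg = weight_ga if weight_ga.seed is not None else GAConfig(
        **{**weight_ga.__dict__, "seed": int(rng.integers(2**31))}
    )
    result = ga_maximize(fitness, "simplex", len(names), ga_cfg)
    weights = {name: float(w) for name, w in zip(names, result.best_chromosome)}
    return EnsembleModel(base_models, weights)


def predict_ensemble(model: EnsembleModel, features: dict[str, FeatureTable]) -> ScoreMatrix:
    """Weighted sum of the base FS-MLKNN predictions for the query drugs."""
    missing = set(model.base_models) - set(features)
    if missing:
        raise ValidationError(f"query is missing feature types: {sorted(missing)}")
    names = list(model.base_models)
    mats = [predict_fs_mlknn(model.base_models[n], features[n]) for n in names]
    w = np.array([model.weights[n] for n in names])
    return weighted_score(w, mats)
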