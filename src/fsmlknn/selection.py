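"""Two-stage feature selection wrapped around MLKNN (FS-MLKNN).

Stage 1 (filter): for every feature dimension v_i, compute the mutual
information I(v_i; d_j) against every side-effect label d_j over the
empirical 2x2 joint, aggregate by the maximum over labels, and keep the
dimensions whose score strictly exceeds a threshold sigma (default 0.001).

Stage 2 (wrapper): a genetic algorithm searches binary chromosomes over the
filtered dimensions; a chromosome's fitness is the merged (micro) AUPR of
MLKNN restricted to its dimensions under an internal 5-fold cross-validation
of the training drugs.  The final FS-MLKNN model consists of five MLKNN
submodels, one per internal fold (each fitted on that fold's 4/5 training
portion, restricted to the chosen dimensions); predictions are the mean of
the five submodel score matrices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import FeatureTable, LabelTable
from .errors import ConfigurationError, ValidationError
from .ga import GAConfig, GAResult, ga_maximize
from .metrics import micro_aupr_arrays
from .mlknn import (
    MLKNNConfig,
    MLKNNModel,
    ScoreMatrix,
    _fit_arrays,
    fit_mlknn,
    knn_indices,
    membership_counts,
    predict_scores,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MIScores",
    "FSMLKNNModel",
    "mutual_information",
    "mi_filter",
    "ga_select_dims",
    "fit_fs_mlknn",
    "predict_fs_mlknn",
    "dim_frequency",
    "internal_folds",
]

DEFAULT_SIGMA = 0.001


@dataclass
class MIScores:
    dim_ids: list[str]
    scores: np.ndarray  # per-dimension max-over-labels MI, bits by default
    sigma: float
    selected: list[str]
    fallback_used: bool = False


@dataclass
class FSMLKNNModel:
    """Selected dimension subset plus five fold-trained MLKNN submodels."""

    feature_name: str
    candidate_dims: list[str]
    chosen_dims: list[str]
    submodels: list[MLKNNModel]
    fold_assignment: np.ndarray  # internal fold index per training drug
    mi_scores: MIScores | None = None
    fitness_trace: list[float] = field(default_factory=list)
    mlknn_config: MLKNNConfig = MLKNNConfig()

    def __post_init__(self) -> None:
        if not self.chosen_dims:
            raise ValidationError("FS-MLKNN model requires a nonempty chosen dimension set")
        if not set(self.chosen_dims) <= set(self.candidate_dims):
            raise ValidationError("chosen_dims must be a subset of candidate_dims")


def _mi_from_counts(n11: np.ndarray, n10: np.ndarray, n01: np.ndarray, n00: np.ndarray, base: float) -> np.ndarray:
    """Plug-in MI from 2x2 cell counts; zero-probability cells contribute 0."""
    n = n11 + n10 + n01 + n00
    total = np.log(base)
    out = np.zeros(np.broadcast(n11, n00).shape, dtype=float)
    for nxy, nx, ny in (
        (n11, n11 + n10, n11 + n01),
        (n10, n11 + n10, n10 + n00),
        (n01, n01 + n00, n11 + n01),
        (n00, n01 + n00, n10 + n00),
    ):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (nxy / n) * np.log((nxy * n) / (nx * ny))
        out += np.where(nxy > 0, term, 0.0)
    return out / total


def mutual_information(dim_column: np.ndarray, label_column: np.ndarray, base: float = 2.0) -> float:
    """MI between two binary vectors over their empirical 2x2 joint (bits by default)."""
    x = np.asarray(dim_column).ravel()
    y = np.asarray(label_column).ravel()
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValidationError("empty vectors")
    n11 = float(np.sum((x == 1) & (y == 1)))
    n10 = float(np.sum((x == 1) & (y == 0)))
    n01 = float(np.sum((x == 0) & (y == 1)))
    n00 = float(np.sum((x == 0) & (y == 0)))
    return float(_mi_from_counts(np.array(n11), np.array(n10), np.array(n01), np.array(n00), base))


def mi_filter(
    features: FeatureTable, labels: LabelTable, sigma: float = DEFAULT_SIGMA, base: float = 2.0
) -> MIScores:
    """Per-dimension score = max over labels of I(v_i; d_j); keep scores > sigma.

    If no dimension passes the threshold, falls back to the top ceil(p/10)
    dimensions by score (logged) so downstream stages always have candidates.
    """
    if features.drug_ids != labels.drug_ids:
        raise ValidationError("feature and label tables must share drug order")
    F = features.values.astype(np.float64)  # (n, p)
    Y = labels.values.astype(np.float64)  # (n, q)
    n = F.shape[0]
    n11 = F.T @ Y  # (p, q)
    n10 = F.sum(0)[:, None] - n11
    n01 = Y.sum(0)[None, :] - n11
    n00 = n - n11 - n10 - n01
    mi = _mi_from_counts(n11, n10, n01, n00, base)  # (p, q)
    scores = mi.max(axis=1) if mi.shape[1] else np.zeros(F.shape[1])
    mask = scores > sigma
    fallback = False
    if not mask.any():
        top = math.ceil(len(scores) / 10)
        keep = np.argsort(-scores, kind="stable")[:top]
        mask = np.zeros_like(mask)
        mask[keep] = True
        fallback = True
        logger.warning("mi_filter: no dimension exceeded sigma=%g; falling back to top %d", sigma, top)
    selected = [d for d, m in zip(features.dim_ids, mask) if m]
    return MIScores(list(features.dim_ids), scores, sigma, selected, fallback)


def internal_folds(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition of n drugs into n_folds near-equal folds (sizes differ by <= 1)."""
    assignment = np.arange(n) % n_folds
    return assignment[rng.permutation(n)]


def _cv_micro_aupr(X: np.ndarray, Y: np.ndarray, folds: np.ndarray, config: MLKNNConfig) -> float:
    """Merged AUPR of MLKNN out-of-fold scores under the given fold assignment."""
    n, q = Y.shape
    oof = np.zeros((n, q))
    cols = np.arange(q)
    for f in np.unique(folds):
        tr = folds != f
        te = ~tr
        priors, post_pos, post_neg, _, _ = _fit_arrays(X[tr], Y[tr], config)
        nn = knn_indices(X[tr], X[te], config.k, exclude_self=False, metric=config.distance)
        C = membership_counts(nn, Y[tr])
        lp = priors[None, :] * post_pos[cols, C]
        ln = (1.0 - priors)[None, :] * post_neg[cols, C]
        oof[te] = lp / (lp + ln)
    return micro_aupr_arrays(oof, Y)


def ga_select_dims(
    features: FeatureTable,
    labels: LabelTable,
    ga: GAConfig = GAConfig(),
    mlknn: MLKNNConfig = MLKNNConfig(),
    seed: int | None = None,
    fold_assignment: np.ndarray | None = None,
) -> tuple[list[str], GAResult]:
    """GA wrapper search over the candidate dimensions of ``features``.

    Fitness of a chromosome is the internal 5-fold-CV merged AUPR of MLKNN
    restricted to the chromosome's dimensions; the all-zero chromosome has
    fitness 0.  Returns the best chromosome's dimension ids and the GA result
    (including the per-generation best-fitness trace).
    """
    if features.n_dims < 1:
        raise ConfigurationError("need at least one candidate dimension")
    rng = np.random.default_rng(seed)
    if fold_assignment is None:
        fold_assignment = internal_folds(features.n_drugs, 5, rng)
    X = features.values
    Y = labels.values

    def fitness(chrom: np.ndarray) -> float:
        idx = np.flatnonzero(chrom)
        if idx.size == 0:
            return 0.0
        return _cv_micro_aupr(X[:, idx], Y, fold_assignment, mlknn)

    ga_cfg = ga if ga.seed is not None else GAConfig(**{**ga.__dict__, "seed": int(rng.integers(2**31))})
    result = ga_maximize(fitness, "binary", features.n_dims, ga_cfg)
    if not result.best_chromosome.any():
        # only possible if every chromosome scored 0; keep all candidates
        result.best_chromosome = np.ones(features.n_dims, dtype=np.int8)
    chosen = [d for d, b in zip(features.dim_ids, result.best_chromosome) if b]
    return chosen, result


def fit_fs_mlknn(
    features: FeatureTable,
    labels: LabelTable,
    sigma: float = DEFAULT_SIGMA,
    ga: GAConfig = GAConfig(),
    mlknn: MLKNNConfig = MLKNNConfig(),
    seed: int | None = None,
) -> FSMLKNNModel:
    """MI filter, GA wrapper, then five fold-trained MLKNN submodels."""
    n = features.n_drugs
    if n < 10:
        raise ConfigurationError(f"FS-MLKNN needs >= 10 training drugs to form 5 internal folds, got {n}")
    rng = np.random.default_rng(seed)
    mi = mi_filter(features, labels, sigma)
    restricted = features.restrict_dims(mi.selected)
    folds = internal_folds(n, 5, rng)
    chosen, result = ga_select_dims(
        restricted, labels, ga, mlknn, seed=int(rng.integers(2**31)), fold_assignment=folds
    )
    final = features.restrict_dims(chosen)
    submodels = []
    for f in range(5):
        keep = folds != f
        ids = [d for d, m in zip(features.drug_ids, keep) if m]
        sub = fit_mlknn(final.restrict_drugs(ids), labels.restrict_drugs(ids), mlknn)
        submodels.append(sub)
    return FSMLKNNModel(
        feature_name=features.feature_name,
        candidate_dims=mi.selected,
        chosen_dims=chosen,
        submodels=submodels,
        fold_assignment=folds,
        mi_scores=mi,
        fitness_trace=result.trace,
        mlknn_config=mlknn,
    )


def predict_fs_mlknn(model: FSMLKNNModel, query: FeatureTable) -> ScoreMatrix:
    """Mean of the five submodel score matrices on the query drugs."""
    sub_query = query.restrict_dims(model.chosen_dims)
    mats = [predict_scores(m, sub_query) for m in model.submodels]
    mean = np.mean([m.scores for m in mats], axis=0)
    return ScoreMatrix(list(query.drug_ids), list(model.submodels[0].label_ids), mean)


def dim_frequency(models: list[FSMLKNNModel]) -> tuple[dict[str, int], list[int]]:
    """How often each dimension was chosen across outer-fold models.

    Returns (per-dimension count over models, per-model chosen-dimension counts).
    """
    if not models:
        raise ValidationError("need at least one model")
    freq: dict[str, int] = {}
    for m in models:
        for d in m.chosen_dims:
            freq[d] = freq.get(d, 0) + 1
    per_model = [len(m.chosen_dims) for m in models]
    return freq, per_model
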