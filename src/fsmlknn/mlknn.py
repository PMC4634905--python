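"""Multi-label k-nearest-neighbor learner (MLKNN).

For each side-effect label l, MLKNN combines a smoothed prior P(H1_l) — the
training frequency of the label — with the likelihood P(E_j_l | H_b_l) of
observing exactly j label-positive drugs among a drug's k nearest neighbors,
and predicts by maximum a posteriori:

    y_t(l) = argmax_{b in {0,1}} P(H_b_l) * P(E_{C_t(l)}_l | H_b_l)

where C_t(l) counts label-positive neighbors of the test drug t.  All
estimates use additive (Laplace-style) smoothing with factor s:

    P(H1_l)         = (s + sum_i y_i(l)) / (2 s + n)
    P(E_j_l | H1_l) = (s + c_l[j])  / (s (k+1) + sum_j c_l[j])
    P(E_j_l | H0_l) = (s + c'_l[j]) / (s (k+1) + sum_j c'_l[j])

c_l[j] counts training drugs that carry label l and have exactly j
label-positive neighbors (the drug itself never counts as its own neighbor);
c'_l[j] counts the same among drugs lacking the label.

The real-valued score reported for ranking metrics is the normalized
posterior P(H1 | E) = P(H1) P(E|H1) / [P(H1) P(E|H1) + P(H0) P(E|H0)],
which is > 0.5 exactly when the MAP rule outputs 1 (a tie yields 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import FeatureTable, LabelTable
from .errors import ConfigurationError, ValidationError

__all__ = [
    "MLKNNConfig",
    "MLKNNModel",
    "ScoreMatrix",
    "knn_indices",
    "membership_counts",
    "fit_mlknn",
    "predict_scores",
    "map_labels",
]


@dataclass(frozen=True)
class MLKNNConfig:
    """MLKNN hyper-parameters: neighbor count ``k``, smoothing factor ``s``, distance."""

    k: int = 5
    s: float = 1.0
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")
        if not self.s > 0:
            raise ConfigurationError(f"smoothing factor s must be > 0, got {self.s}")
        if self.distance not in ("euclidean", "jaccard", "cosine"):
            raise ConfigurationError(f"unknown distance {self.distance!r}")


@dataclass
class ScoreMatrix:
    """Real-valued prediction scores in [0, 1], drugs x side effects."""

    drug_ids: list[str]
    label_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.drug_ids), len(self.label_ids)):
            raise ValidationError(
                f"score matrix shape {self.scores.shape} does not match ids "
                f"({len(self.drug_ids)} x {len(self.label_ids)})"
            )
        if not np.isfinite(self.scores).all():
            raise ValidationError("score matrix contains non-finite values")


@dataclass
class MLKNNModel:
    """Fitted MLKNN: stored training instances plus smoothed priors/posteriors.

    ``post_pos[l, j]`` is P(E_j | H1) for label l, ``post_neg[l, j]`` is
    P(E_j | H0); ``counts_pos`` / ``counts_neg`` retain the raw c_l / c'_l
    for inspection.
    """

    config: MLKNNConfig
    train_features: np.ndarray
    train_labels: np.ndarray
    train_dim_ids: list[str]
    label_ids: list[str]
    priors: np.ndarray  # (q,) P(H1_l)
    post_pos: np.ndarray  # (q, k+1)
    post_neg: np.ndarray  # (q, k+1)
    counts_pos: np.ndarray = field(repr=False, default=None)
    counts_neg: np.ndarray = field(repr=False, default=None)


def _pairwise_distances(train: np.ndarray, query: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        # squared Euclidean: same neighbor ordering, exact integer arithmetic
        # for binary data so equidistant ties are bitwise ties
        t = train.astype(np.float64)
        q = query.astype(np.float64)
        d2 = q.sum(1)[:, None] + t.sum(1)[None, :] - 2.0 * q @ t.T
        np.maximum(d2, 0.0, out=d2)
        return d2
    return cdist(query.astype(float), train.astype(float), metric=metric)


def knn_indices(
    train_features: np.ndarray,
    query_features: np.ndarray,
    k: int,
    exclude_self: bool = False,
    metric: str = "euclidean",
) -> np.ndarray:
    """Indices of the k nearest training rows for each query row.

    With ``exclude_self`` the query is assumed to be the training matrix and
    row i never returns itself.  Ties between equidistant training rows are
    broken toward the lower training-row index, making the result
    deterministic.
    """
    train_features = np.asarray(train_features)
    query_features = np.asarray(query_features)
    n_train = train_features.shape[0]
    n_eligible = n_train - 1 if exclude_self else n_train
    if k > n_eligible:
        raise ConfigurationError(f"k={k} exceeds the {n_eligible} eligible training rows")
    d = _pairwise_distances(train_features, query_features, metric)
    if exclude_self:
        if query_features.shape[0] != n_train:
            raise ValidationError("exclude_self requires query == training set")
        np.fill_diagonal(d, np.inf)
    # stable argsort: among equal distances the lower index comes first
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def membership_counts(neighbor_indices: np.ndarray, train_labels: np.ndarray) -> np.ndarray:
    """C_x(l): number of a drug's k nearest neighbors that carry label l."""
    neighbor_indices = np.asarray(neighbor_indices)
    train_labels = np.asarray(train_labels)
    return train_labels[neighbor_indices].sum(axis=1)


def _fit_arrays(X: np.ndarray, Y: np.ndarray, config: MLKNNConfig) -> tuple[np.ndarray, ...]:
    n = X.shape[0]
    k, s = config.k, config.s
    if k >= n:
        raise ConfigurationError(f"k={k} requires at least k+1={k + 1} training drugs, got {n}")
    priors = (s + Y.sum(axis=0)) / (s * 2 + n)

    nn = knn_indices(X, X, k, exclude_self=True, metric=config.distance)
    C = membership_counts(nn, Y)  # (n, q)

    q = Y.shape[1]
    c_pos = np.zeros((q, k + 1))
    c_neg = np.zeros((q, k + 1))
    Yb = Y.astype(bool)
    for j in range(k + 1):
        at_j = C == j
        c_pos[:, j] = (at_j & Yb).sum(axis=0)
        c_neg[:, j] = (at_j & ~Yb).sum(axis=0)
    post_pos = (s + c_pos) / (s * (k + 1) + c_pos.sum(axis=1, keepdims=True))
    post_neg = (s + c_neg) / (s * (k + 1) + c_neg.sum(axis=1, keepdims=True))
    return priors, post_pos, post_neg, c_pos, c_neg


def fit_mlknn(train: FeatureTable, labels: LabelTable, config: MLKNNConfig = MLKNNConfig()) -> MLKNNModel:
    """Fit MLKNN on aligned feature and label tables."""
    if train.drug_ids != labels.drug_ids:
        raise ValidationError("feature and label tables must share drug order (use align_bundle)")
    priors, post_pos, post_neg, c_pos, c_neg = _fit_arrays(train.values, labels.values, config)
    return MLKNNModel(
        config=config,
        train_features=train.values.copy(),
        train_labels=labels.values.copy(),
        train_dim_ids=list(train.dim_ids),
        label_ids=list(labels.label_ids),
        priors=priors,
        post_pos=post_pos,
        post_neg=post_neg,
        counts_pos=c_pos,
        counts_neg=c_neg,
    )


def predict_scores(model: MLKNNModel, query: FeatureTable) -> ScoreMatrix:
    """Normalized posterior P(H1 | E_{C_t(l)}) per test drug and label."""
    if list(query.dim_ids) != model.train_dim_ids:
        raise ValidationError("query feature dimensions do not match the fitted model")
    nn = knn_indices(
        model.train_features, query.values, model.config.k, exclude_self=False, metric=model.config.distance
    )
    C = membership_counts(nn, model.train_labels)  # (n_query, q)
    q = len(model.label_ids)
    cols = np.arange(q)
    like_pos = model.priors[None, :] * model.post_pos[cols, C]
    like_neg = (1.0 - model.priors)[None, :] * model.post_neg[cols, C]
    scores = like_pos / (like_pos + like_neg)
    return ScoreMatrix(list(query.drug_ids), list(model.label_ids), scores)


def map_labels(scores: ScoreMatrix) -> np.ndarray:
    """MAP binary labels from scores: 1 iff score > 0.5 (posterior tie -> 0)."""
    return (scores.scores > 0.5).astype(np.int8)
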