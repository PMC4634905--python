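"""Cross-validation and independent train/test protocols.

``run_cv`` implements repeated outer 5-fold cross-validation: per repeat the
drugs are randomly split into five near-equal subsets; each subset in turn
is held out while the model — plain MLKNN, FS-MLKNN (with feature selection
re-run inside each outer training set), or the weighted ensemble — is
fitted on the remaining four.  Out-of-fold scores are concatenated and the
metric suite is evaluated once per repeat on the merged predictions;
means and standard deviations are reported across repeats (and, for
reference, across all folds).

``run_independent`` fits the ensemble on a training bundle and scores a
disjoint test bundle, reporting merged AUPR/AUC and top-N recalls.

Everything that involves randomness (fold splits, GA seeds) derives from a
single plan seed, so a manifest is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import DatasetBundle, FeatureTable
from .ensemble import EnsembleModel, fit_ensemble, predict_ensemble
from .errors import ConfigurationError, LeakageError, ValidationError
from .ga import GAConfig
from .metrics import EvaluationReport, evaluate_scores, topn_recall
from .mlknn import MLKNNConfig, ScoreMatrix, fit_mlknn, predict_scores
from .selection import fit_fs_mlknn, internal_folds, predict_fs_mlknn

__all__ = ["CVPlan", "RunManifest", "run_cv", "run_independent"]

METHODS = ("mlknn", "fs_mlknn", "ensemble")


@dataclass(frozen=True)
class CVPlan:
    """Outer cross-validation plan: fold count, repeats, and the master seed."""

    n_folds: int = 5
    n_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")

    def assignments(self, n_drugs: int) -> np.ndarray:
        """(n_repeats, n_drugs) fold index per drug per repeat; sizes differ by <= 1."""
        rng = np.random.default_rng(self.seed)
        return np.stack([internal_folds(n_drugs, self.n_folds, rng) for _ in range(self.n_repeats)])


@dataclass
class RunManifest:
    method: str
    config: dict
    seed: int
    dataset_digest: str
    per_repeat_reports: list[EvaluationReport]
    per_fold_reports: list[EvaluationReport]
    mean: dict[str, float]
    sd: dict[str, float]
    sd_across_folds: dict[str, float]
    per_fold_chosen_dims: list[dict] = field(default_factory=list)
    per_fold_weights: list[dict] = field(default_factory=list)
    oof_scores: list[ScoreMatrix] = field(default_factory=list, repr=False)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "config": self.config,
            "seed": self.seed,
            "dataset_digest": self.dataset_digest,
            "per_repeat_reports": [r.to_dict() for r in self.per_repeat_reports],
            "per_fold_reports": [r.to_dict() for r in self.per_fold_reports],
            "mean": self.mean,
            "sd": self.sd,
            "sd_across_folds": self.sd_across_folds,
            "per_fold_chosen_dims": self.per_fold_chosen_dims,
            "per_fold_weights": self.per_fold_weights,
            "extras": self.extras,
        }
        return d


def _subset_bundle(bundle: DatasetBundle, drug_ids: list[str]) -> DatasetBundle:
    return DatasetBundle(
        {n: ft.restrict_drugs(drug_ids) for n, ft in bundle.features.items()},
        bundle.labels.restrict_drugs(drug_ids),
    )


def _aggregate(reports: list[EvaluationReport]) -> tuple[dict, dict]:
    keys = [k for k in EvaluationReport.__dataclass_fields__ if k != "n_labels_evaluated"]
    mean = {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}
    sd = {k: float(np.std([getattr(r, k) for r in reports], ddof=1)) if len(reports) > 1 else 0.0 for k in keys}
    return mean, sd


def run_cv(
    bundle: DatasetBundle,
    method: str,
    plan: CVPlan = CVPlan(),
    feature_name: str | None = None,
    mlknn: MLKNNConfig = MLKNNConfig(),
    sigma: float = 0.001,
    fs_ga: GAConfig = GAConfig(),
    weight_ga: GAConfig = GAConfig(),
) -> RunManifest:
    """Repeated outer 5-CV of one method on a bundle; returns a reproducible manifest.

    ``feature_name`` picks the feature table for the single-feature methods
    (``mlknn``, ``fs_mlknn``); the ensemble always uses every feature type.
    All feature selection and weight tuning happens inside each outer
    training set only; a leakage guard verifies the partition.
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}; expected one of {METHODS}")
    if method != "ensemble":
        if feature_name is None:
            feature_name = next(iter(bundle.features))
        if feature_name not in bundle.features:
            raise ValidationError(f"no feature table named {feature_name!r}")
    drug_ids = bundle.labels.drug_ids
    n = len(drug_ids)
    if n < plan.n_folds * (mlknn.k + 1):
        raise ConfigurationError(
            f"need at least n_folds*(k+1) = {plan.n_folds * (mlknn.k + 1)} drugs, got {n}"
        )
    assignments = plan.assignments(n)
    seed_rng = np.random.default_rng(plan.seed + 1)

    per_repeat, per_fold = [], []
    chosen_dims_log, weights_log, oof_list = [], [], []
    for r in range(plan.n_repeats):
        folds = assignments[r]
        oof = np.zeros((n, bundle.labels.n_labels))
        for f in range(plan.n_folds):
            tr_ids = [d for d, m in zip(drug_ids, folds != f) if m]
            te_ids = [d for d, m in zip(drug_ids, folds == f) if m]
            if set(tr_ids) & set(te_ids):
                raise LeakageError("train/test drug sets overlap")
            train = _subset_bundle(bundle, tr_ids)
            fit_seed = int(seed_rng.integers(2**31))
            if method == "mlknn":
                model = fit_mlknn(train.features[feature_name], train.labels, mlknn)
                _guard_ids(te_ids, model.train_features.shape[0], tr_ids)
                sm = predict_scores(model, bundle.features[feature_name].restrict_drugs(te_ids))
            elif method == "fs_mlknn":
                model = fit_fs_mlknn(train.features[feature_name], train.labels, sigma, fs_ga, mlknn, fit_seed)
                chosen_dims_log.append({"repeat": r, "fold": f, "chosen_dims": model.chosen_dims})
                sm = predict_fs_mlknn(model, bundle.features[feature_name].restrict_drugs(te_ids))
            else:
                model = fit_ensemble(train, sigma, fs_ga, weight_ga, mlknn, fit_seed)
                chosen_dims_log.append(
                    {"repeat": r, "fold": f, "chosen_dims": {k: m.chosen_dims for k, m in model.base_models.items()}}
                )
                weights_log.append({"repeat": r, "fold": f, "weights": model.weights})
                sm = predict_ensemble(model, {k: ft.restrict_drugs(te_ids) for k, ft in bundle.features.items()})
            oof[folds == f] = sm.scores
            per_fold.append(evaluate_scores(sm.scores, bundle.labels.restrict_drugs(te_ids).values))
        oof_sm = ScoreMatrix(list(drug_ids), list(bundle.labels.label_ids), oof)
        oof_list.append(oof_sm)
        per_repeat.append(evaluate_scores(oof, bundle.labels.values))

    mean, sd = _aggregate(per_repeat)
    _, sd_folds = _aggregate(per_fold)
    config = {
        "mlknn": {"k": mlknn.k, "s": mlknn.s, "distance": mlknn.distance},
        "sigma": sigma,
        "fs_ga": fs_ga.__dict__ if method != "mlknn" else None,
        "weight_ga": weight_ga.__dict__ if method == "ensemble" else None,
        "feature_name": feature_name,
        "plan": {"n_folds": plan.n_folds, "n_repeats": plan.n_repeats, "seed": plan.seed},
    }
    return RunManifest(
        method=method,
        config=config,
        seed=plan.seed,
        dataset_digest=bundle.digest(),
        per_repeat_reports=per_repeat,
        per_fold_reports=per_fold,
        mean=mean,
        sd=sd,
        sd_across_folds=sd_folds,
        per_fold_chosen_dims=chosen_dims_log,
        per_fold_weights=weights_log,
        oof_scores=oof_list,
    )


def _guard_ids(test_ids: list[str], n_train_rows: int, train_ids: list[str]) -> None:
    if n_train_rows != len(train_ids):
        raise LeakageError("training structure size does not match the training drug set")
    if set(test_ids) & set(train_ids):
        raise LeakageError("test drug found in a training structure")


def run_independent(
    train_bundle: DatasetBundle,
    test_bundle: DatasetBundle,
    mlknn: MLKNNConfig = MLKNNConfig(),
    sigma: float = 0.001,
    fs_ga: GAConfig = GAConfig(),
    weight_ga: GAConfig = GAConfig(),
    seed: int = 0,
    top_ns: tuple[int, ...] = (100, 200),
) -> RunManifest:
    """Fit the ensemble on the training drugs, score the disjoint test drugs.

    Reports the merged AUPR/AUC on the test set plus mean top-N recalls
    (N capped at the label count) and per-drug correctly-predicted
    side-effect counts.
    """
    overlap = set(train_bundle.drug_ids) & set(test_bundle.drug_ids)
    if overlap:
        raise ValidationError(f"train and test drug sets overlap: {sorted(overlap)[:5]}")
    if set(train_bundle.features) != set(test_bundle.features):
        raise ValidationError("train and test bundles must share feature types")
    if train_bundle.labels.label_ids != test_bundle.labels.label_ids:
        raise ValidationError("train and test bundles must share the label set")

    model = fit_ensemble(train_bundle, sigma, fs_ga, weight_ga, mlknn, seed)
    sm = predict_ensemble(model, test_bundle.features)
    Y = test_bundle.labels.values
    report = evaluate_scores(sm.scores, Y)

    q = test_bundle.labels.n_labels
    recalls = {}
    per_drug_records = []
    for n_top in top_ns:
        n_top_eff = min(n_top, q)
        per_drug, mean_recall = topn_recall(sm.scores, Y, n_top_eff)
        recalls[f"top{n_top}"] = {"mean_recall": mean_recall, "n_top_used": n_top_eff}
        if n_top == top_ns[0]:
            n_known = Y.sum(axis=1)
            n_correct = np.where(np.isnan(per_drug), 0, per_drug * n_known).round().astype(int)
            per_drug_records = [
                {
                    "drug_id": d,
                    "n_known_side_effects": int(kk),
                    "n_correct_in_top": int(cc),
                    "recall": None if np.isnan(rr) else float(rr),
                }
                for d, kk, cc, rr in zip(test_bundle.drug_ids, n_known, n_correct, per_drug)
            ]

    mean, sd = _aggregate([report])
    return RunManifest(
        method="independent_ensemble",
        config={
            "mlknn": {"k": mlknn.k, "s": mlknn.s, "distance": mlknn.distance},
            "sigma": sigma,
            "fs_ga": fs_ga.__dict__,
            "weight_ga": weight_ga.__dict__,
        },
        seed=seed,
        dataset_digest=train_bundle.digest() + ":" + test_bundle.digest(),
        per_repeat_reports=[report],
        per_fold_reports=[report],
        mean=mean,
        sd=sd,
        sd_across_folds=sd,
        per_fold_chosen_dims=[{"chosen_dims": {k: m.chosen_dims for k, m in model.base_models.items()}}],
        per_fold_weights=[{"weights": model.weights}],
        oof_scores=[sm],
        extras={"topn_recall": recalls, "per_drug": per_drug_records},
    )
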