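"""Multi-label evaluation metrics.

The suite covers the two threshold-free merged metrics (micro AUPR, micro
AUC — all drug-label pairs pooled into one ranking), the classic multi-label
ranking metrics of Zhang & Zhou (one-error, coverage, ranking loss, average
precision), Hamming loss on thresholded labels, per-label AUPR with the
three-way method comparison, and top-N recall for independent test sets.

Side-effect data are severely imbalanced (far more negative than positive
drug-label pairs), so AUPR is the headline metric: AUC is dominated by the
easy negatives while AUPR rewards precision among the top-ranked pairs.

Conventions: AUPR is the non-interpolated step area (average-precision
form), with tied scores collapsed into one precision/recall step; AUC uses
the rank-sum estimator with tie correction; coverage is unnormalized
(0 .. q-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError, ValidationError
from .mlknn import ScoreMatrix

__all__ = [
    "EvaluationReport",
    "micro_aupr",
    "micro_aupr_arrays",
    "micro_auc",
    "ranking_metrics",
    "hamming_loss",
    "per_label_aupr",
    "compare_methods",
    "topn_recall",
    "evaluate_scores",
]


@dataclass
class EvaluationReport:
    aupr: float
    auc: float
    hamming_loss: float
    ranking_loss: float
    one_error: float
    coverage: float
    average_precision: float
    n_labels_evaluated: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _check_pair(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValidationError(f"shape mismatch: scores {scores.shape} vs truth {truth.shape}")
    return scores, truth


def _step_aupr(scores: np.ndarray, truth: np.ndarray) -> float:
    """Non-interpolated step AUPR; tied scores enter the curve as one block."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = truth[order].astype(float)
    n_pos = y.sum()
    if n_pos == 0:
        raise UndefinedMetricError("AUPR undefined: no positive pairs")
    # block boundaries where the score strictly drops
    boundaries = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    ends = np.append(boundaries, s.size - 1)  # inclusive end index of each tied block
    cum_pos = np.cumsum(y)[ends]
    cum_tot = ends + 1.0
    precision = cum_pos / cum_tot
    recall = cum_pos / n_pos
    d_recall = np.diff(np.concatenate(([0.0], recall)))
    return float(np.sum(d_recall * precision))


def micro_aupr_arrays(scores: np.ndarray, truth: np.ndarray) -> float:
    scores, truth = _check_pair(scores, truth)
    return _step_aupr(scores.ravel(), truth.ravel())


def _as_arrays(scores, truth) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(scores, ScoreMatrix):
        scores = scores.scores
    if hasattr(truth, "values") and not isinstance(truth, np.ndarray):
        truth = truth.values
    return _check_pair(scores, truth)


def micro_aupr(scores, truth) -> float:
    """Merged AUPR over all drug-label pairs pooled into one ranking."""
    s, y = _as_arrays(scores, truth)
    return _step_aupr(s.ravel(), y.ravel())


def micro_auc(scores, truth) -> float:
    """Merged AUC via the rank-sum (Mann-Whitney) estimator with tie correction."""
    s, y = _as_arrays(scores, truth)
    s, y = s.ravel(), y.ravel().astype(bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: needs both classes")
    ranks = rankdata(s)  # average ranks for ties
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def ranking_metrics(scores, truth) -> tuple[float, float, float, float]:
    """(one_error, coverage, ranking_loss, average_precision), Zhang-Zhou style.

    Per instance: one_error — top-scored label not relevant; coverage — rank
    of the deepest relevant label minus 1 (unnormalized); ranking_loss —
    fraction of (relevant, irrelevant) pairs ordered wrongly (ties count
    half); average_precision — mean over relevant labels of the fraction of
    relevant labels at or above that label's rank.  Instances with no
    relevant labels are skipped for one_error/ranking_loss/AP and contribute
    coverage 0.
    """
    S, Y = _as_arrays(scores, truth)
    one_errors, coverages, rlosses, aps = [], [], [], []
    for s, y in zip(S, Y):
        rel = y.astype(bool)
        n_rel = int(rel.sum())
        n_irr = y.size - n_rel
        # coverage: every instance contributes (0 when nothing is relevant)
        if n_rel == 0:
            coverages.append(0.0)
            continue
        # ranks: 1 = best score; ties get the worst (max) rank for coverage,
        # average rank for AP, and pairwise comparison for ranking loss
        desc = -s
        max_rank = rankdata(desc, method="max")
        coverages.append(float(max_rank[rel].max() - 1))
        top = np.flatnonzero(s == s.max())[0]  # deterministic tie-break: lowest index
        one_errors.append(0.0 if rel[top] else 1.0)
        if n_irr > 0:
            rs = s[rel][:, None]
            is_ = s[~rel][None, :]
            wrong = (rs < is_).sum() + 0.5 * (rs == is_).sum()
            rlosses.append(float(wrong) / (n_rel * n_irr))
        avg_rank = rankdata(desc, method="average")
        rel_ranks = avg_rank[rel]
        ap_terms = [(rel_ranks <= r).sum() / r for r in rel_ranks]
        aps.append(float(np.mean(ap_terms)))
    one_error = float(np.mean(one_errors)) if one_errors else 0.0
    coverage = float(np.mean(coverages)) if coverages else 0.0
    ranking_loss = float(np.mean(rlosses)) if rlosses else 0.0
    average_precision = float(np.mean(aps)) if aps else 0.0
    return one_error, coverage, ranking_loss, average_precision


def hamming_loss(predicted, truth) -> float:
    """Fraction of drug-label cells where the thresholded prediction disagrees with truth."""
    p, y = _as_arrays(predicted, truth)
    return float(np.mean(p.astype(int) != y.astype(int)))


def per_label_aupr(scores, truth) -> np.ndarray:
    """AUPR per label column; labels with zero positive drugs are NaN (undefined)."""
    S, Y = _as_arrays(scores, truth)
    out = np.full(S.shape[1], np.nan)
    for l in range(S.shape[1]):
        if Y[:, l].sum() > 0:
            out[l] = _step_aupr(S[:, l], Y[:, l])
    return out


def compare_methods(per_label_a: np.ndarray, per_label_b: np.ndarray) -> tuple[int, int, int]:
    """Three-way counts (a > b, a == b, b > a) over labels defined for both methods."""
    a = np.asarray(per_label_a, dtype=float)
    b = np.asarray(per_label_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("per-label vectors must have equal length")
    if not np.array_equal(np.isnan(a), np.isnan(b)):
        raise ValidationError("methods must be defined on the same label set")
    ok = ~np.isnan(a)
    a, b = a[ok], b[ok]
    return int((a > b).sum()), int((a == b).sum()), int((b > a).sum())


def topn_recall(scores, truth, n_top: int) -> tuple[np.ndarray, float]:
    """Per-drug recall of the top ``n_top`` scored labels, and its mean.

    Recall of drug i = |relevant(i) ∩ top-n_top(i)| / |relevant(i)|.  Drugs
    with no relevant labels are skipped (NaN in the per-drug vector); ties at
    the cutoff are broken by label index.
    """
    S, Y = _as_arrays(scores, truth)
    if n_top > S.shape[1]:
        raise ValidationError(f"n_top={n_top} exceeds the {S.shape[1]} labels")
    per_drug = np.full(S.shape[0], np.nan)
    for i in range(S.shape[0]):
        rel = np.flatnonzero(Y[i])
        if rel.size == 0:
            continue
        top = np.argsort(-S[i], kind="stable")[:n_top]
        per_drug[i] = np.intersect1d(rel, top).size / rel.size
    defined = per_drug[~np.isnan(per_drug)]
    mean = float(defined.mean()) if defined.size else float("nan")
    return per_drug, mean


def evaluate_scores(scores, truth, threshold: float = 0.5) -> EvaluationReport:
    """Full report: merged AUPR/AUC, Hamming loss at ``threshold``, ranking metrics."""
    S, Y = _as_arrays(scores, truth)
    one_error, coverage, ranking_loss, ap = ranking_metrics(S, Y)
    return EvaluationReport(
        aupr=micro_aupr(S, Y),
        auc=micro_auc(S, Y),
        hamming_loss=hamming_loss((S > threshold).astype(int), Y),
        ranking_loss=ranking_loss,
        one_error=one_error,
        coverage=coverage,
        average_precision=ap,
        n_labels_evaluated=int((Y.sum(axis=0) > 0).sum()),
    )
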