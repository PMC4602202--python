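"""Rank-based evaluation metrics for variant prioritization.

The central quantity is the *rank ratio* of a positive test variant: its
rank in a candidate list divided by the list length (lower is better).
Averaging rank ratios within a disease and then across diseases gives the
mean rank ratio (MRR).  Per disease, a rank-ROC curve is traced over the
distinct rank-ratio thresholds — sensitivity is the fraction of positive
variants at or below the threshold, specificity the fraction of negative
variants above it — and the area under it (AUC) is averaged across
diseases.  A score-threshold false-positive rate and a one-sided
hypergeometric top-k enrichment test complete the framework.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InputError


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for a top-k enrichment test.

    ``N`` candidates in total, ``K`` of them functional, ``n`` in the top
    of the ranking, ``x`` functional among those top ``n``.
    """

    N: int
    K: int
    n: int
    x: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.x <= min(self.K, self.n) <= self.N
            and self.K <= self.N
            and self.n <= self.N
        )
        if not ok:
            raise InputError(
                f"invalid enrichment counts N={self.N}, K={self.K}, "
                f"n={self.n}, x={self.x}"
            )


def rank_of_positive(pos_score: float, neg_scores: Sequence[float]) -> float:
    """Rank of a positive among negatives, averaging over ties.

    rank = 1 + #{negatives strictly above} + half the ties.
    """
    neg = np.asarray(neg_scores, dtype=float)
    return float(1 + np.sum(neg > pos_score) + 0.5 * np.sum(neg == pos_score))


def rank_ratio(rank: float, total: int) -> float:
    """Rank divided by the candidate-list length; in (0, 1]."""
    if not 1 <= rank <= total:
        raise InputError(f"rank {rank} outside [1, {total}]")
    return rank / total


def mean_rank_ratio(per_disease: Mapping[str, Sequence[float]]) -> float:
    """Two-stage unweighted mean: within disease, then across diseases."""
    if not per_disease:
        raise InputError("no diseases to average over")
    means = []
    for disease, ratios in per_disease.items():
        if len(ratios) == 0:
            raise InputError(f"disease {disease!r} has no rank ratios")
        means.append(float(np.mean(ratios)))
    return float(np.mean(means))


def rank_roc_auc(
    pos_ratios: Sequence[float], neg_ratios: Sequence[float]
) -> float:
    """Area under the rank-ROC curve for one disease.

    The curve is traced over the distinct observed rank-ratio values plus
    the endpoints {0, 1}: sensitivity(t) = fraction of positives with
    ratio <= t, specificity(t) = fraction of negatives with ratio > t.
    The trapezoidal area equals the Mann-Whitney probability
    P(pos < neg) + 0.5 P(pos = neg).
    """
    pos = np.asarray(pos_ratios, dtype=float)
    neg = np.asarray(neg_ratios, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InputError("both positive and negative rank ratios are required")
    thresholds = np.unique(np.concatenate([[0.0, 1.0], pos, neg]))
    sens = (pos[None, :] <= thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] <= thresholds[:, None]).mean(axis=1)  # 1 - specificity
    return float(np.trapezoid(sens, fpr))


def mean_auc(per_disease_auc: Mapping[str, float]) -> float:
    """Unweighted mean of per-disease rank-ROC AUCs."""
    if not per_disease_auc:
        raise InputError("no diseases to average over")
    return float(np.mean(list(per_disease_auc.values())))


def false_positive_rate(
    neutral_scores: Mapping[str, Sequence[float]], threshold: float
) -> float:
    """Mean over diseases of the fraction of neutral scores >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise InputError(f"threshold {threshold} outside [0, 1]")
    props = []
    for scores in neutral_scores.values():
        s = np.asarray(scores, dtype=float)
        props.append(float(np.mean(s >= threshold)) if s.size else 0.0)
    if not props:
        raise InputError("no diseases with neutral scores")
    return float(np.mean(props))


def random_guess_expected_topk(n_pos: int, n_neg: int, k: int) -> float:
    """Expected number of positives ranked in the top ``k`` by chance.

    Each positive is prioritized independently against the ``n_neg``
    negatives and lands uniformly on one of ``n_neg + 1`` positions, so
    the expectation is ``n_pos * min(k, n_neg + 1) / (n_neg + 1)``.
    """
    if k < 1 or n_neg < 0 or n_pos < 0:
        raise InputError("k must be >= 1 and counts non-negative")
    total = n_neg + 1
    return n_pos * min(k, total) / total


def hypergeom_topk_enrichment(e: EnrichmentInput) -> float:
    """One-sided enrichment tail P(X >= x) for top-k functional counts.

    X ~ Hypergeometric(N, K, n): the number of functional candidates in a
    random size-``n`` subset of the ``N`` candidates.  Equivalent to a
    one-sided Fisher exact test on the top-k contingency table; evaluated
    through log-gamma based survival functions, never raw factorials.
    """
    return float(stats.hypergeom.sf(e.x - 1, e.N, e.K, e.n))


def ranks_in_list(scores: Sequence[float]) -> np.ndarray:
    """Descending-score ranks with average-rank ties (1 = best)."""
    s = np.asarray(scores, dtype=float)
    return stats.rankdata(-s, method="average")
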