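"""Validation machinery: ROC/AUROC, spike-in ranking, singleton enrichment,
and score-vs-allele-frequency tail contrasts.

AUROC is computed by the rank-based Mann-Whitney identity with ties counted
as half wins, i.e. the probability that a random positive outscores a random
negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn import metrics as skm

from .intervals import DataError


def auroc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative (ties = 0.5)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DataError("auroc needs non-empty score lists")
    ranks = sps.rankdata(np.concatenate([pos, neg]), method="average")
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class RocCurve:
    """Sensitivity over false positive rate, plus the area under the curve."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float


def roc_curve(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> RocCurve:
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DataError("roc_curve needs non-empty score lists")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, thr = skm.roc_curve(y, np.concatenate([pos, neg]))
    return RocCurve(thr, tpr, fpr, auroc(pos, neg))


@dataclass
class SpikeInRank:
    """Percentile rank of a spiked-in variant within one individual's SV set."""

    rank: float
    top_5pct: bool


def spike_in_rank(
    pathogenic_score: float, individual_scores: Sequence[float], top_frac: float = 0.05
) -> SpikeInRank:
    """Rank of a known-pathogenic score among one individual's SV scores.

    Uses strict-greater counting with add-one smoothing,
    ``rank = (1 + #strictly greater) / (n + 1)``, so the rank is never zero
    and ties do not penalise the spike-in.
    """
    scores = np.asarray(individual_scores, dtype=float)
    greater = int(np.sum(scores > pathogenic_score))
    rank = (1 + greater) / (scores.size + 1)
    return SpikeInRank(rank=float(rank), top_5pct=bool(rank <= top_frac))


def singleton_enrichment(
    scores: Sequence[float],
    allele_counts: Sequence[int],
    top_frac: float = 0.05,
) -> float:
    """P(singleton | score in top fraction) / P(singleton overall).

    A ratio above 1 in the pathogenic tail is the signature of purifying
    selection keeping deleterious variants rare.
    """
    scores = np.asarray(scores, dtype=float)
    ac = np.asarray(allele_counts)
    if scores.size == 0:
        raise DataError("empty cohort")
    k = math.ceil(top_frac * scores.size)
    if k == 0:
        raise DataError("top score bin is empty")
    top = np.argsort(-scores, kind="stable")[:k]
    p_all = float(np.mean(ac == 1))
    if p_all == 0.0:
        raise DataError("no singletons in the cohort; enrichment undefined")
    p_top = float(np.mean(ac[top] == 1))
    return p_top / p_all


def tail_af_contrast(
    scores: Sequence[float],
    allele_frequencies: Sequence[float],
    tail_frac: float = 0.05,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney test of allele frequency, top vs bottom score tail.

    Under purifying selection the top (putatively deleterious) tail should
    carry lower allele frequencies.  Uses the normal approximation with tie
    correction (the tails in use are large); returns (statistic, p-value).
    """
    scores = np.asarray(scores, dtype=float)
    af = np.asarray(allele_frequencies, dtype=float)
    if scores.size != af.size:
        raise DataError("scores and allele frequencies differ in length")
    k = math.ceil(tail_frac * scores.size)
    if k < 2:
        raise DataError("tail bins need at least 2 records each")
    order = np.argsort(-scores, kind="stable")
    top_af = af[order[:k]]
    bottom_af = af[order[-k:]]
    res = sps.mannwhitneyu(
        top_af, bottom_af, alternative="two-sided", method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)
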