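"""Consensus and reliability analysis of two-rater Likert score sheets.

Each of the eight dose-adaptation criteria is scored 1-5 by two independent
raters (1 = very poor … 5 = very good). The consensus per criterion is the
median score rounded to the nearest integer — with two raters a one-level
disagreement gives a half-integer median, which rounds half-up toward the
better rating by default (a half-even switch exists for sensitivity
analysis). The overall rating is the unweighted mean of the criterion
consensus values, rounded the same way. Inter-rater reliability is a
Cronbach alpha with the raters as the test components and the criteria as
observations.
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

import numpy as np

from .fixtures import LIKERT_LABELS


class DegenerateScoresError(ValueError):
    """Reliability is undefined because the scores carry no variance."""


def _check_scores(scores: Sequence[int]) -> None:
    for s in scores:
        if int(s) != s or not (1 <= s <= 5):
            raise ValueError(f"Likert score {s!r} outside integer range 1-5")


def _round(value: float, ties: Literal["half_up", "half_even"]) -> int:
    if ties == "half_even":
        return int(round(value))
    return int(math.floor(value + 0.5))


def consensus_rating(
    scores_for_item: Sequence[int],
    ties: Literal["half_up", "half_even"] = "half_up",
) -> int:
    """Median of the raters' scores for one criterion, rounded to integer."""
    if not scores_for_item:
        raise ValueError("no scores supplied")
    _check_scores(scores_for_item)
    return _round(float(np.median(scores_for_item)), ties)


def overall_rating(
    consensus_by_criterion: Sequence[int],
    ties: Literal["half_up", "half_even"] = "half_up",
) -> int:
    """Unweighted mean of criterion consensus scores, rounded to integer."""
    if not consensus_by_criterion:
        raise ValueError("no consensus scores supplied")
    _check_scores(consensus_by_criterion)
    return _round(float(np.mean(consensus_by_criterion)), ties)


def likert_label(score: int) -> str:
    return LIKERT_LABELS[score]


def cronbach_alpha(scores: np.ndarray) -> float:
    """Cronbach alpha over a raters × items score matrix.

    alpha = k/(k−1) × (1 − Σ_i var(rater_i) / var(Σ_i rater_i)), with the
    k raters as components scored across the items and sample variances
    (n − 1). Zero variance of the rater sums leaves alpha undefined.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D raters × items matrix")
    k, n_items = scores.shape
    if k < 2 or n_items < 2:
        raise ValueError("need at least 2 raters and 2 items")
    total_var = np.var(scores.sum(axis=0), ddof=1)
    if total_var == 0:
        raise DegenerateScoresError("rater-sum variance is zero; alpha undefined")
    rater_vars = np.var(scores, axis=1, ddof=1)
    return float(k / (k - 1) * (1.0 - rater_vars.sum() / total_var))


def disagreement_count(scores: np.ndarray) -> int:
    """Number of criteria on which the two raters differ."""
    scores = np.asarray(scores)
    if scores.ndim != 2 or scores.shape[0] != 2:
        raise ValueError("expected a 2 × items score matrix")
    return int(np.sum(scores[0] != scores[1]))
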