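"""Fisher-score (F_score) feature ranking and mean-threshold selection.

For feature i with positive/negative class samples x(+), x(-):

            (mean_i(+) - mean_i)^2 + (mean_i(-) - mean_i)^2
    F(i) = -------------------------------------------------
            var_i(+) + var_i(-)          (sample variances, n-1 denominator)

Larger F(i) means larger between-class separation relative to within-class
spread.  Selection keeps the features scoring strictly above the mean of
the finite scores, ranked in descending order.  A feature that is constant
within each class but differs between classes has zero denominator and a
nonzero numerator; it receives an infinite score, sorts first, and is
excluded from the mean so it cannot inflate the threshold.

F_score is location- and scale-invariant per feature and symmetric under
swapping the class labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["FScoreResult", "fscore", "select", "fit_selection"]

logger = logging.getLogger(__name__)


@dataclass
class FScoreResult:
    scores: np.ndarray
    n_pos: int
    n_neg: int
    mean_score: float
    order: np.ndarray  # all feature indices, kept first, descending score
    mask: np.ndarray  # True where score > mean_score

    @property
    def n_kept(self) -> int:
        return int(self.mask.sum())


def fscore(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature F_score of a binary-labelled sample matrix.

    ``y`` may be boolean or any two-valued labelling; the positive class
    is ``True``/the greater label.  Both classes need >= 2 samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes!r}")
    pos = y == classes[-1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("each class needs at least 2 samples (n-1 variance denominator)")
    Xp, Xn = X[pos], X[~pos]
    m, mp, mn = X.mean(axis=0), Xp.mean(axis=0), Xn.mean(axis=0)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = Xp.var(axis=0, ddof=1) + Xn.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    zero_den = den == 0
    if zero_den.any():
        # constant-within-class feature: perfectly separating if means differ
        f[zero_den & (num > 0)] = np.inf
        f[zero_den & (num == 0)] = 0.0
        n_inf = int(np.isinf(f).sum())
        if n_inf:
            logger.info("%d feature(s) with zero within-class variance scored +inf", n_inf)
    return f


def select(scores: np.ndarray, n_pos: int = 0, n_neg: int = 0) -> FScoreResult:
    """Mean-threshold selection: keep scores strictly above the finite mean.

    Returns the full descending ranking (kept features first).  Raises if
    every score is equal, since no feature then clears the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if np.all(scores == scores[0]):
        raise ValueError("no discriminative features: all scores equal")
    finite = np.isfinite(scores)
    mean_score = float(scores[finite].mean()) if finite.any() else 0.0
    mask = (scores > mean_score) | ~finite
    if not mask.any():
        raise ValueError("no discriminative features: nothing above the mean score")
    # stable descending sort; +inf sorts first
    desc = np.argsort(-scores, kind="stable")
    order = np.concatenate([desc[mask[desc]], desc[~mask[desc]]])
    return FScoreResult(
        scores=scores, n_pos=n_pos, n_neg=n_neg,
        mean_score=mean_score, order=order, mask=mask,
    )


def fit_selection(X: np.ndarray, y: np.ndarray) -> FScoreResult:
    """Score and select in one step on a training partition."""
    classes = np.unique(y)
    pos = np.asarray(y) == classes[-1]
    f = fscore(X, y)
    return select(f, n_pos=int(pos.sum()), n_neg=int((~pos).sum()))
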