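"""Rank-order (normal scores) transform and its empirical back-transform."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import ndtri

from ..errors import DegenerateDataError, ValidationError

__all__ = ["NormalScoresMap", "normal_scores_transform", "normal_scores_backtransform"]


@dataclass
class NormalScoresMap:
    """Empirical value <-> score graph used for back-transformation.

    ``values`` are the sorted distinct data values; ``scores`` are the
    corresponding normal scores (strictly increasing).  Ties in the data share
    an average rank and hence a single knot.
    """

    values: np.ndarray
    scores: np.ndarray
    tie_policy: str = "average-rank"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.values) != len(self.scores):
            raise ValidationError("values and scores must have equal length")
        if np.any(np.diff(self.scores) <= 0):
            raise ValidationError("normal scores must be strictly increasing")


def normal_scores_transform(values: np.ndarray) -> tuple[np.ndarray, NormalScoresMap]:
    """Map data to standard-normal quantiles of Hazen plotting positions.

    Scores are ``Phi^-1((r - 0.5) / n)`` with ``r`` the (average, for ties)
    rank.  Order is preserved; tied values receive a shared score.
    """
    z = np.asarray(values, dtype=float)
    if z.ndim != 1:
        raise ValidationError("values must be one-dimensional")
    if len(z) < 3:
        raise ValidationError("normal scores transform needs n >= 3 values")
    if not np.all(np.isfinite(z)):
        raise ValidationError("values must all be finite")
    if np.ptp(z) == 0:
        raise DegenerateDataError("all values identical: no rank information")
    n = len(z)
    ranks = stats.rankdata(z, method="average")
    scores = ndtri((ranks - 0.5) / n)
    uniq_vals, first_idx = np.unique(z, return_index=True)
    mapping = NormalScoresMap(values=uniq_vals, scores=scores[first_idx])
    return scores, mapping


def normal_scores_backtransform(scores: np.ndarray, mapping: NormalScoresMap) -> np.ndarray:
    """Piecewise-linear inverse of the score -> value graph.

    Scores outside the observed score range clamp to the min/max observed
    value; scores at stored knots return the stored value exactly.
    """
    if mapping is None or len(mapping.values) == 0:
        raise ValidationError("back-transform requires a populated NormalScoresMap")
    s = np.asarray(scores, dtype=float)
    return np.interp(s, mapping.scores, mapping.values)
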