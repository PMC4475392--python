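"""Ordinary kriging with a global neighbourhood, plus leave-one-out machinery.

Kriging operates on (rank-transformed) scores; predictions can be
back-transformed to original units through a :class:`NormalScoresMap` while
kriging variances stay in rank space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from ..errors import DecompositionError, ValidationError
from .transforms import NormalScoresMap, normal_scores_backtransform
from .variogram import VariogramModel, matern_correlation, matern_covariance

__all__ = ["KrigingSurface", "ordinary_kriging", "loo_cross_validate", "covariance_matrix"]


@dataclass
class KrigingSurface:
    """Predictions and kriging variances on a set of target locations."""

    grid_xy: np.ndarray
    predictions: np.ndarray  # original units when a back-transform map is given
    score_predictions: np.ndarray  # rank-space predictions
    variances: np.ndarray  # rank-space kriging variances
    model: VariogramModel

    def __post_init__(self) -> None:
        if np.any(self.variances < -1e-8):
            raise ValidationError("kriging variances must be nonnegative")


def covariance_matrix(site_xy: np.ndarray, model: VariogramModel) -> np.ndarray:
    """Covariance matrix at the sites: c1*rho(d) off-diagonal, sill on diagonal."""
    xy = np.asarray(site_xy, dtype=float)
    n = len(xy)
    C = model.partial_sill * matern_correlation(squareform(pdist(xy)), model.range_, model.smoothness)
    C[np.diag_indices(n)] = model.sill
    return C


def _check_duplicates(xy: np.ndarray, site_ids=None) -> None:
    _, inverse, counts = np.unique(
        np.round(xy, decimals=9), axis=0, return_inverse=True, return_counts=True
    )
    if np.any(counts > 1):
        dup_groups = []
        for g in np.nonzero(counts > 1)[0]:
            members = np.nonzero(inverse == g)[0]
            names = [str(site_ids[i]) if site_ids is not None else str(i) for i in members]
            dup_groups.append("(" + ", ".join(names) + ")")
        raise ValidationError(
            "coincident site coordinates make the kriging system singular: "
            + "; ".join(dup_groups)
        )


def _bordered_system(site_xy: np.ndarray, model: VariogramModel) -> np.ndarray:
    n = len(site_xy)
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = covariance_matrix(site_xy, model)
    K[n, :n] = 1.0
    K[:n, n] = 1.0
    K[n, n] = 0.0
    return K


def ordinary_kriging(
    site_xy: np.ndarray,
    scores: np.ndarray,
    model: VariogramModel,
    grid_xy: np.ndarray,
    ns_map: NormalScoresMap | None = None,
    site_ids=None,
) -> KrigingSurface:
    """Ordinary kriging at ``grid_xy`` using every site (global neighbourhood).

    Solves the bordered covariance system with the unbiasedness constraint
    (weights sum to 1 via a Lagrange multiplier).  The nugget is included in
    the cross-covariance at exactly coincident locations, so a zero-nugget
    model interpolates the data exactly.
    """
    xy = np.asarray(site_xy, dtype=float)
    z = np.asarray(scores, dtype=float)
    gxy = np.atleast_2d(np.asarray(grid_xy, dtype=float))
    _check_duplicates(xy, site_ids)
    n = len(xy)
    K = _bordered_system(xy, model)
    try:
        from scipy.linalg import lu_factor, lu_solve

        lu = lu_factor(K)
    except Exception as exc:  # pragma: no cover - singular beyond duplicates
        raise DecompositionError(f"kriging system factorization failed: {exc}") from exc

    Dc = cdist(xy, gxy)
    c = model.partial_sill * matern_correlation(Dc, model.range_, model.smoothness)
    c[Dc <= 1e-12] += model.nugget
    rhs = np.vstack([c, np.ones((1, gxy.shape[0]))])
    sol = lu_solve(lu, rhs)
    w, mu = sol[:n], sol[n]
    score_pred = w.T @ z
    var = model.sill - np.einsum("ij,ij->j", w, c) - mu
    var = np.where(var < 0, np.where(var > -1e-8, 0.0, var), var)
    pred = (
        normal_scores_backtransform(score_pred, ns_map) if ns_map is not None else score_pred
    )
    return KrigingSurface(
        grid_xy=gxy,
        predictions=pred,
        score_predictions=score_pred,
        variances=var,
        model=model,
    )


def _loo_blocks(site_xy: np.ndarray, model: VariogramModel):
    """Top-left block Q of the inverse bordered kriging matrix."""
    K = _bordered_system(np.asarray(site_xy, dtype=float), model)
    try:
        Kinv = np.linalg.inv(K)
    except np.linalg.LinAlgError as exc:
        raise DecompositionError(f"kriging system is singular: {exc}") from exc
    n = len(site_xy)
    Q = Kinv[:n, :n]
    return Q, np.diag(Q).copy()


def loo_cross_validate(
    site_xy: np.ndarray,
    scores: np.ndarray,
    model: VariogramModel,
    site_ids=None,
):
    """Leave-one-out kriging: per-site prediction, variance and SSPE theta.

    Uses the classical shortcut through the inverse of the bordered kriging
    matrix: with Q its top-left n x n block, the held-out error is
    ``(Q z)_i / Q_ii`` and the held-out kriging variance ``1 / Q_ii``.
    theta_i = (z_i - zhat_{-i})^2 / sigma^2_{-i}.

    Returns ``(predictions, variances, theta, flagged)`` where ``flagged``
    marks sites whose held-out variance was not positive (theta set to NaN).
    """
    xy = np.asarray(site_xy, dtype=float)
    z = np.asarray(scores, dtype=float)
    if len(z) < 10:
        raise ValidationError("leave-one-out validation needs n >= 10 sites")
    _check_duplicates(xy, site_ids)
    Q, dQ = _loo_blocks(xy, model)
    flagged = dQ <= 1e-12
    dQ_safe = np.where(flagged, 1.0, dQ)
    err = (Q @ z) / dQ_safe  # z_i - zhat_{-i}
    sigma2 = 1.0 / dQ_safe
    theta = err**2 / sigma2
    pred = z - err
    sigma2 = np.where(flagged, np.nan, sigma2)
    theta = np.where(flagged, np.nan, theta)
    return pred, sigma2, theta, flagged
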