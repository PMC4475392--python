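"""SSPE model validation: chi-square reference plus simulation-based limits.

Under a correct model the leave-one-out standardized squared prediction
errors follow a chi-square distribution with one degree of freedom, which has
mean 1 and median 0.455.  Observed mean/median SSPE are compared against
95% limits obtained from unconditional simulations of the fitted model at the
data locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import DecompositionError, ValidationError
from .kriging import _loo_blocks, covariance_matrix
from .variogram import VariogramModel

__all__ = ["CrossValidationReport", "sspe_diagnostics", "simulate_sspe_statistics"]

CHI2_1_MEAN = 1.0
CHI2_1_MEDIAN = 0.455  # median of chi-square(1), 0.4549 to 4 decimals


@dataclass
class CrossValidationReport:
    theta: np.ndarray | None  # observed per-site SSPE (None if no data given)
    mean: float | None
    median: float | None
    mean_limits: tuple[float, float]
    median_limits: tuple[float, float]
    verdict: str  # "within" | "outside" | "no-data"
    n_simulations: int = 0
    reference_mean: float = CHI2_1_MEAN
    reference_median: float = CHI2_1_MEDIAN
    space: str = "rank"  # SSPE computed in rank (normal-score) space
    sim_means: np.ndarray = field(default=None, repr=False)
    sim_medians: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for lo, hi in (self.mean_limits, self.median_limits):
            if not lo < hi:
                raise ValidationError("confidence limits must satisfy low < high")

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "median": self.median,
            "mean_limits": list(self.mean_limits),
            "median_limits": list(self.median_limits),
            "verdict": self.verdict,
            "n_simulations": self.n_simulations,
            "reference_mean": self.reference_mean,
            "reference_median": self.reference_median,
            "space": self.space,
        }


def simulate_sspe_statistics(
    site_xy: np.ndarray,
    model: VariogramModel,
    n_sim: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-simulation LOO SSPE mean and median for fields drawn from ``model``.

    Fields are simulated unconditionally at the data locations (the model is
    not refitted per simulation) and cross-validated with the same model.
    """
    xy = np.asarray(site_xy, dtype=float)
    n = len(xy)
    C = covariance_matrix(xy, model)
    C[np.diag_indices(n)] += 1e-10 * model.sill
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise DecompositionError(
            "covariance not positive definite for "
            f"(c0={model.nugget}, c1={model.partial_sill}, a={model.range_}, "
            f"v={model.smoothness}): {exc}"
        ) from exc
    rng = np.random.default_rng(seed)
    Z = L @ rng.standard_normal((n, n_sim))
    Q, dQ = _loo_blocks(xy, model)
    good = dQ > 1e-12
    theta = (Q @ Z)[good] ** 2 / dQ[good, None]
    return theta.mean(axis=0), np.median(theta, axis=0)


def sspe_diagnostics(
    site_xy: np.ndarray,
    model: VariogramModel,
    scores: np.ndarray | None = None,
    n_sim: int = 1000,
    seed: int = 0,
) -> CrossValidationReport:
    """SSPE validation report with simulated 95% limits for mean and median."""
    if n_sim < 100:
        raise ValidationError("sspe_diagnostics needs at least 100 simulations")
    xy = np.asarray(site_xy, dtype=float)
    sim_means, sim_medians = simulate_sspe_statistics(xy, model, n_sim, seed=seed)
    mean_limits = tuple(np.percentile(sim_means, [2.5, 97.5]))
    median_limits = tuple(np.percentile(sim_medians, [2.5, 97.5]))

    theta = obs_mean = obs_median = None
    verdict = "no-data"
    if scores is not None:
        from .kriging import loo_cross_validate

        _, _, theta, flagged = loo_cross_validate(xy, scores, model)
        ok = ~flagged
        obs_mean = float(np.mean(theta[ok]))
        obs_median = float(np.median(theta[ok]))
        within = (
            mean_limits[0] <= obs_mean <= mean_limits[1]
            and median_limits[0] <= obs_median <= median_limits[1]
        )
        verdict = "within" if within else "outside"
    return CrossValidationReport(
        theta=theta,
        mean=obs_mean,
        median=obs_median,
        mean_limits=mean_limits,
        median_limits=median_limits,
        verdict=verdict,
        n_simulations=n_sim,
        sim_means=sim_means,
        sim_medians=sim_medians,
    )
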