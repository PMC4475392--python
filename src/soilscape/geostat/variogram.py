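"""Matérn variograms: empirical estimation, model evaluation and fitting.

The Matérn semivariance used throughout is

    gamma(h) = c0 + c1 * (1 - (2**(1-v) / Gamma(v)) * (h/a)**v * K_v(h/a)),  h > 0
    gamma(0) = 0

with nugget ``c0``, partial sill ``c1``, range parameter ``a`` and smoothness
``v`` (``v = 0.5`` reduces to the exponential model).  Fitting is available by
weighted nonlinear least squares on an empirical variogram or by maximum
likelihood on the data directly (stationary Gaussian model, constant unknown
mean handled by profiling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.spatial.distance import pdist

from ..errors import FittingError, ValidationError

__all__ = [
    "VariogramModel",
    "EmpiricalVariogram",
    "matern_correlation",
    "matern_semivariance",
    "matern_covariance",
    "empirical_variogram",
    "fit_variogram",
    "effective_range",
]


@dataclass
class VariogramModel:
    """Matérn variogram parameters plus fitting diagnostics.

    Attributes
    ----------
    nugget : float
        Micro-scale + error variance ``c0 >= 0``.
    partial_sill : float
        Spatially structured variance ``c1 >= 0``.
    range_ : float
        Distance-scale parameter ``a > 0`` (metres).
    smoothness : float
        Matérn smoothness ``v > 0``.
    method : str or None
        ``"wls"`` or ``"ml"`` when fitted; ``None`` for a-priori models.
    objective : float or None
        Objective value at the optimum (WLS sum of squares or negative
        log-likelihood).
    at_bounds : bool
        True when the optimiser finished on a parameter bound.
    """

    nugget: float
    partial_sill: float
    range_: float
    smoothness: float
    method: str | None = None
    objective: float | None = None
    at_bounds: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.nugget) or self.nugget < 0:
            raise ValidationError(f"nugget must be finite and >= 0, got {self.nugget}")
        if not np.isfinite(self.partial_sill) or self.partial_sill < 0:
            raise ValidationError(
                f"partial_sill must be finite and >= 0, got {self.partial_sill}"
            )
        if not np.isfinite(self.range_) or self.range_ <= 0:
            raise ValidationError(f"range_ must be finite and > 0, got {self.range_}")
        if not np.isfinite(self.smoothness) or self.smoothness <= 0:
            raise ValidationError(
                f"smoothness must be finite and > 0, got {self.smoothness}"
            )

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def to_dict(self) -> dict:
        return {
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "range": self.range_,
            "smoothness": self.smoothness,
            "method": self.method,
            "objective": self.objective,
            "at_bounds": self.at_bounds,
        }


@dataclass
class EmpiricalVariogram:
    """Method-of-moments variogram estimate per distance bin.

    ``gamma`` is NaN for bins with no pairs (``n_pairs == 0``) — empty bins are
    reported, never zero-filled.
    """

    lags: np.ndarray  # bin centres (metres), strictly increasing
    gamma: np.ndarray  # semivariance estimates, NaN where n_pairs == 0
    n_pairs: np.ndarray  # integer pair counts per bin
    max_lag: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValidationError("lag bin centres must be strictly increasing")
        if np.any(self.n_pairs < 0):
            raise ValidationError("pair counts must be nonnegative")
        populated = self.n_pairs > 0
        if np.any(self.gamma[populated] < 0):
            raise ValidationError("semivariance estimates must be nonnegative")


def matern_correlation(h, range_: float, smoothness: float) -> np.ndarray:
    """Matérn correlation rho(h); rho(0) = 1, decaying to 0 with distance."""
    h = np.asarray(h, dtype=float)
    x = h / float(range_)
    v = float(smoothness)
    out = np.ones_like(x)
    pos = x > 1e-10
    xv = x[pos]
    with np.errstate(over="ignore"):
        vals = (2.0 ** (1.0 - v) / special.gamma(v)) * xv**v * special.kv(v, xv)
    # kv underflows to 0 at large arguments, which is the correct limit
    vals = np.nan_to_num(vals, nan=0.0, posinf=1.0)
    out[pos] = np.clip(vals, 0.0, 1.0)
    return out


def matern_semivariance(h, model: VariogramModel) -> np.ndarray:
    """Semivariance gamma(h) of the model; gamma(0) = 0 by definition."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValidationError("lag distances must be >= 0")
    rho = matern_correlation(h, model.range_, model.smoothness)
    gamma = model.nugget + model.partial_sill * (1.0 - rho)
    return np.where(h == 0.0, 0.0, gamma)


def matern_covariance(h, model: VariogramModel) -> np.ndarray:
    """Covariance C(h) = c1*rho(h) + c0*1{h=0} (nugget active only at h = 0)."""
    h = np.asarray(h, dtype=float)
    rho = matern_correlation(h, model.range_, model.smoothness)
    cov = model.partial_sill * rho
    return np.where(h == 0.0, cov + model.nugget, cov)


def empirical_variogram(
    site_xy: np.ndarray,
    values: np.ndarray,
    n_bins: int = 15,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Method-of-moments empirical variogram on equal-width distance bins.

    gamma_hat(bin) = sum over pairs in bin of (z_i - z_j)^2 / (2 N(bin));
    pairs farther apart than ``max_lag`` are excluded.  Default ``max_lag`` is
    half the maximum inter-site distance.
    """
    xy = np.asarray(site_xy, dtype=float)
    z = np.asarray(values, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValidationError("site_xy must be an (n, 2) array")
    if len(z) != len(xy):
        raise ValidationError("values length must match site count")
    if len(xy) < 2:
        raise ValidationError("need at least 2 sites")
    d = pdist(xy)
    if max_lag is None:
        max_lag = 0.5 * float(d.max())
    if max_lag <= 0:
        raise ValidationError("max_lag must be > 0")
    dz2 = pdist(z[:, None], metric="sqeuclidean")
    width = max_lag / n_bins
    keep = (d > 0) & (d <= max_lag)
    # bin k covers (k*width, (k+1)*width]
    idx = np.ceil(d[keep] / width).astype(int) - 1
    np.clip(idx, 0, n_bins - 1, out=idx)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=dz2[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = sums / (2.0 * counts)
    gamma[counts == 0] = np.nan
    centres = (np.arange(n_bins) + 0.5) * width
    return EmpiricalVariogram(centres, gamma, counts, max_lag=max_lag)


def _wls_objective(params, lags, gamma_hat, weights, fix_v):
    c0, c1, a = params[:3]
    v = fix_v if fix_v is not None else params[3]
    model_gamma = c0 + c1 * (1.0 - matern_correlation(lags, a, v))
    return np.sqrt(weights) * (gamma_hat - model_gamma)


def _profile_nll(log_params, dist_matrix, z, fix_v):
    """Negative profile log-likelihood (constant mean profiled out by GLS).

    Parameters arrive on the log scale, which conditions the optimizer far
    better than raw values spanning several orders of magnitude.
    """
    c0, c1, a = np.exp(log_params[:3])
    v = fix_v if fix_v is not None else np.exp(log_params[3])
    n = len(z)
    if c1 <= 0 or a <= 0 or c0 < 0 or v <= 0:
        return np.inf
    C = c1 * matern_correlation(dist_matrix, a, v)
    C[np.diag_indices(n)] += c0 + 1e-10 * (c0 + c1)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ones = np.ones(n)
    zi = np.linalg.solve(L, np.column_stack([z, ones]))
    zz, oz = zi[:, 0], zi[:, 1]
    mu = oz @ zz / (oz @ oz)
    r = zz - mu * oz
    return 0.5 * (logdet + r @ r + n * np.log(2.0 * np.pi))


_PARAM_ORDER = ("nugget", "partial_sill", "range", "smoothness")


def _apply_bounds(lo, hi, bounds, fix_smoothness):
    """Override default box bounds from a {param: (lo, hi)} mapping."""
    if not bounds:
        return lo, hi
    lo, hi = list(lo), list(hi)
    names = _PARAM_ORDER[:3] if fix_smoothness is not None else _PARAM_ORDER
    for name, (b_lo, b_hi) in bounds.items():
        if name not in names:
            raise ValidationError(f"unknown or fixed bound parameter {name!r}")
        i = names.index(name)
        lo[i], hi[i] = float(b_lo), float(b_hi)
    return lo, hi


def fit_variogram(
    empirical: EmpiricalVariogram | None = None,
    method: str = "wls",
    site_xy: np.ndarray | None = None,
    values: np.ndarray | None = None,
    fix_smoothness: float | None = None,
    bounds: dict | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> VariogramModel:
    """Fit a Matérn variogram by WLS (on bins) or ML (on the data).

    WLS minimises ``sum N(h) * (gamma_hat - gamma(h; theta))^2``; ML maximises
    the stationary multivariate-normal log-likelihood with constant unknown
    mean.  The best of ``n_starts`` seeded starts is returned with its
    objective; a model that finished on a bound carries ``at_bounds=True``.
    """
    rng = np.random.default_rng(seed)
    if method == "wls":
        if empirical is None:
            raise ValidationError("wls fitting requires an EmpiricalVariogram")
        ok = (empirical.n_pairs > 0) & np.isfinite(empirical.gamma)
        if ok.sum() < 4:
            raise ValidationError(
                f"wls fitting needs >= 4 populated bins, got {int(ok.sum())}"
            )
        lags = empirical.lags[ok]
        gh = empirical.gamma[ok]
        w = empirical.n_pairs[ok].astype(float)
        gmax = max(gh.max(), 1e-12)
        hmax = lags.max()
        lo = [0.0, 1e-12, hmax * 1e-3] + ([] if fix_smoothness else [0.05])
        hi = [5 * gmax, 5 * gmax, hmax * 10] + ([] if fix_smoothness else [5.0])
        lo, hi = _apply_bounds(lo, hi, bounds, fix_smoothness)
        base = [0.1 * gmax, 0.9 * gmax, hmax / 3] + ([] if fix_smoothness else [0.5])
        best = None
        for k in range(n_starts):
            p0 = np.asarray(base, dtype=float)
            if k > 0:
                p0 = p0 * rng.lognormal(0.0, 0.5, size=len(p0))
            p0 = np.clip(p0, np.asarray(lo) + 1e-12, hi)
            try:
                res = optimize.least_squares(
                    _wls_objective,
                    p0,
                    bounds=(lo, hi),
                    args=(lags, gh, w, fix_smoothness),
                )
            except Exception:
                continue
            obj = 2.0 * res.cost  # sum of squared weighted residuals
            if best is None or obj < best[0]:
                best = (obj, res.x)
        if best is None:
            raise FittingError("wls variogram fit failed to converge from any start")
        obj, x = best
        at_bounds = bool(
            np.any(np.isclose(x, lo, rtol=1e-6, atol=1e-9))
            or np.any(np.isclose(x, hi, rtol=1e-6))
        )
        v = fix_smoothness if fix_smoothness is not None else x[3]
        return VariogramModel(
            nugget=float(x[0]),
            partial_sill=float(x[1]),
            range_=float(x[2]),
            smoothness=float(v),
            method="wls",
            objective=float(obj),
            at_bounds=at_bounds,
        )

    if method == "ml":
        if site_xy is None or values is None:
            raise ValidationError("ml fitting requires site_xy and values")
        xy = np.asarray(site_xy, dtype=float)
        z = np.asarray(values, dtype=float)
        if len(z) < 20:
            raise ValidationError("ml fitting needs n >= 20 observations")
        from scipy.spatial.distance import squareform

        D = squareform(pdist(xy))
        var = float(np.var(z, ddof=1))
        hmax = float(D.max())
        lo = [1e-8 * var, 1e-8 * var, hmax * 1e-3] + ([] if fix_smoothness else [0.05])
        hi = [10 * var, 10 * var, hmax * 10] + ([] if fix_smoothness else [5.0])
        lo, hi = _apply_bounds(lo, hi, bounds, fix_smoothness)
        base = [0.1 * var, 0.9 * var, hmax / 4] + ([] if fix_smoothness else [0.5])
        log_lo, log_hi = np.log(lo), np.log(hi)
        best = None
        for k in range(n_starts):
            p0 = np.asarray(base, dtype=float)
            if k > 0:
                p0 = p0 * rng.lognormal(0.0, 0.75, size=len(p0))
            p0 = np.clip(np.log(p0), log_lo + 1e-9, log_hi - 1e-9)
            try:
                res = optimize.minimize(
                    _profile_nll,
                    p0,
                    args=(D, z, fix_smoothness),
                    method="L-BFGS-B",
                    bounds=list(zip(log_lo, log_hi)),
                )
            except Exception:
                continue
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best[0]:
                best = (res.fun, res.x)
        if best is None:
            raise FittingError("ml variogram fit failed to converge from any start")
        obj, logx = best
        x = np.exp(logx)
        at_bounds = bool(
            np.any(logx <= log_lo + 1e-6) or np.any(logx >= log_hi - 1e-6)
        )
        v = fix_smoothness if fix_smoothness is not None else x[3]
        return VariogramModel(
            nugget=float(x[0]),
            partial_sill=float(x[1]),
            range_=float(x[2]),
            smoothness=float(v),
            method="ml",
            objective=float(obj),
            at_bounds=at_bounds,
        )

    raise ValidationError(f"unknown fit method {method!r}; expected 'wls' or 'ml'")


def effective_range(model: VariogramModel, fraction: float = 0.95) -> float:
    """Smallest h where gamma(h) - c0 reaches ``fraction`` of the partial sill."""
    if model.partial_sill <= 0:
        raise ValidationError("effective range undefined when partial_sill = 0")
    target = fraction * model.partial_sill

    def f(h):
        rho = matern_correlation(np.asarray([h]), model.range_, model.smoothness)[0]
        return model.partial_sill * (1.0 - rho) - target

    hi = model.range_
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 2.0
    else:
        raise FittingError("could not bracket the effective range")
    return float(optimize.brentq(f, 1e-9 * model.range_, hi, xtol=1e-10 * model.range_))
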