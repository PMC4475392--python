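"""Variance partitioning of taxon abundances and community dissimilarity.

Implements collinearity pruning of predictors, forward selection under a
double criterion (adjusted-R² gain with permutation p-value, plus decreasing
AIC), three-block partial-regression partitioning (soil, land management,
space) and distance-based redundancy analysis on the principal coordinates of
an arbitrary dissimilarity matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import DistanceMatrix
from .errors import ConfigurationError, DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorBlocks",
    "SelectionResult",
    "PartitionResult",
    "prepare_blocks",
    "forward_select",
    "partition_abundance",
    "partition_community",
    "standardized_coefficients",
    "adjusted_r2",
    "log_relative_abundance",
    "principal_coordinates",
]


# ---------------------------------------------------------------------------
# linear-algebra primitives

def _as_matrix(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def _orthobasis(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of a centred matrix."""
    if X.size == 0:
        return np.empty((X.shape[0], 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.empty((X.shape[0], 0))
    return U[:, s > tol * s[0]]


def _r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Unadjusted (multivariate trace) R² of centred Y on centred X, and rank."""
    Yc = Y - Y.mean(axis=0)
    ssy = float(np.sum(Yc**2))
    if ssy == 0:
        raise DegenerateDataError("response has zero variance")
    if X.size == 0:
        return 0.0, 0
    U = _orthobasis(X - X.mean(axis=0))
    proj = U @ (U.T @ Yc)
    return float(np.sum(proj**2) / ssy), U.shape[1]


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment; may be negative and is reported unclipped."""
    if n - m - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _aic(ssy: float, r2: float, n: int, m: int) -> float:
    """n*log(RSS/n) + 2k with k = m predictors + intercept."""
    rss = max(ssy * (1.0 - r2), 1e-300)
    return n * np.log(rss / n) + 2.0 * (m + 1)


# ---------------------------------------------------------------------------
# predictor preparation

@dataclass
class PredictorBlocks:
    """Aligned predictor blocks: numeric soil, dummy-coded management, PCNMs."""

    soil: pd.DataFrame
    management: pd.DataFrame
    space: pd.DataFrame
    pruning_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.soil.index
        for name, block in (("management", self.management), ("space", self.space)):
            if not block.index.equals(idx):
                raise ValidationError(f"{name} block index does not match soil block")
        for name, block in (
            ("soil", self.soil),
            ("management", self.management),
            ("space", self.space),
        ):
            if block.shape[1] and (block.nunique() <= 1).any():
                const = list(block.columns[block.nunique() <= 1])
                raise ValidationError(f"constant columns in {name} block: {const}")


def _prune_collinear(X: pd.DataFrame, threshold: float, log: list[str]) -> pd.DataFrame:
    """Drop collinear columns: exact linear dependencies first, then pairs.

    For an offending pair (or a column fully explained by the others) the
    member with the larger mean absolute correlation to the remaining columns
    is dropped.
    """
    X = X.copy()

    def mean_abs_corr(corr: pd.DataFrame, col: str) -> float:
        others = [c for c in corr.columns if c != col]
        return float(corr.loc[col, others].abs().mean()) if others else 0.0

    # stage 1: exact (near-)linear dependencies, e.g. compositional closures
    while X.shape[1] >= 3:
        Z = (X - X.mean()) / X.std(ddof=1)
        dependent = []
        for col in X.columns:
            others = Z.drop(columns=col).to_numpy()
            r2, _ = _r2(Z[[col]].to_numpy(), others)
            if r2 > 0.999:
                dependent.append(col)
        if not dependent:
            break
        corr = X.corr()
        victim = max(dependent, key=lambda c: mean_abs_corr(corr, c))
        log.append(f"dropped {victim!r}: linearly dependent on remaining predictors")
        X = X.drop(columns=victim)

    # stage 2: pairwise absolute correlation above the threshold
    while X.shape[1] >= 2:
        corr = X.corr()
        tri = corr.where(np.triu(np.ones(corr.shape, dtype=bool), k=1))
        worst = tri.abs().stack().sort_values(ascending=False)
        if worst.empty or worst.iloc[0] < threshold:
            break
        a, b = worst.index[0]
        victim = a if mean_abs_corr(corr, a) >= mean_abs_corr(corr, b) else b
        log.append(
            f"dropped {victim!r}: |r|={worst.iloc[0]:.3f} with "
            f"{(b if victim == a else a)!r} exceeds threshold {threshold}"
        )
        X = X.drop(columns=victim)
    return X


def prepare_blocks(
    site_table: pd.DataFrame,
    pcnm_scores: pd.DataFrame,
    soil_variables: list[str] | None = None,
    management_column: str = "management",
    corr_threshold: float = 0.9,
    reference_level: str | None = None,
) -> PredictorBlocks:
    """Standardize soil predictors, prune collinearity, dummy-code management.

    ``pcnm_scores`` must be indexed alignably with ``site_table`` rows.  The
    management reference level defaults to ``"Forest"`` when present,
    otherwise the alphabetically first level.
    """
    df = site_table.reset_index(drop=True)
    if soil_variables is None:
        exclude = {"site_id", "x", "y", management_column}
        soil_variables = [
            c for c in df.columns if c not in exclude and pd.api.types.is_numeric_dtype(df[c])
        ]
    soil = df[soil_variables].astype(float)
    complete = soil.notna().all(axis=1)
    if not complete.all():
        raise ValidationError(
            f"incomplete soil data at rows {list(df.index[~complete])}"
        )
    log: list[str] = []
    sds = soil.std(ddof=1)
    const = list(sds.index[sds == 0])
    for c in const:
        log.append(f"dropped {c!r}: constant column")
    soil = soil.drop(columns=const)
    soil = _prune_collinear(soil, corr_threshold, log)
    if soil.shape[1] == 0:
        raise ConfigurationError("soil block is empty after collinearity pruning")
    soil = (soil - soil.mean()) / soil.std(ddof=1)

    mgmt_raw = df[management_column].astype(str)
    levels = sorted(mgmt_raw.unique())
    if reference_level is None:
        reference_level = "Forest" if "Forest" in levels else levels[0]
    if reference_level not in levels:
        raise ConfigurationError(f"reference level {reference_level!r} not among {levels}")
    dummies = pd.get_dummies(mgmt_raw, prefix=management_column).astype(float)
    dummies = dummies.drop(columns=f"{management_column}_{reference_level}")
    log.append(f"management reference level: {reference_level!r}")

    space = pcnm_scores.reset_index(drop=True).astype(float)
    if len(space) != len(df):
        raise ValidationError("PCNM scores do not align with the site table")
    return PredictorBlocks(
        soil=soil, management=dummies, space=space, pruning_log=log
    )


# ---------------------------------------------------------------------------
# forward selection

@dataclass
class SelectionResult:
    selected: list[str]
    records: list[dict]  # per step: variable, adj_r2, aic, p_value
    stopping_reason: str

    def __post_init__(self) -> None:
        adj = [r["adj_r2"] for r in self.records]
        if any(b < a - 1e-12 for a, b in zip(adj, adj[1:])):
            raise ValidationError("adjusted R² must be nondecreasing along selection")


def forward_select(
    response,
    block: pd.DataFrame,
    alpha: float = 0.001,
    n_perm: int = 999,
    seed: int = 0,
    require_aic: bool = True,
    max_steps: int | None = None,
) -> SelectionResult:
    """Forward selection with permutation significance and an AIC guard.

    At each step the candidate with the largest adjusted-R² gain is admitted
    if (a) its permutation p-value is <= ``alpha`` and (b) the AIC of the
    grown model decreases.  The permutation null uses the maximum gain over
    all remaining candidates (which keeps the selection-wide false-positive
    rate at ``alpha``); residuals of the current model are permuted.  Passing
    residuals of an environmental model as ``response`` yields the
    residual-based selection of spatial descriptors.
    """
    Y = _as_matrix(response)
    n = len(Y)
    if len(block) != n:
        raise ValidationError("block rows must match the response length")
    Yc = Y - Y.mean(axis=0)
    ssy = float(np.sum(Yc**2))
    if ssy == 0:
        raise DegenerateDataError("response has zero variance")
    Xall = block.to_numpy(dtype=float)
    Xall = Xall - Xall.mean(axis=0)
    names = list(block.columns)
    rng = np.random.default_rng(seed)

    selected: list[int] = []
    records: list[dict] = []
    cur_r2, cur_rank = 0.0, 0
    cur_aic = _aic(ssy, 0.0, n, 0)
    R = Yc.copy()
    reason = "no candidates left"
    while True:
        remaining = [j for j in range(len(names)) if j not in selected]
        if not remaining:
            break
        if max_steps is not None and len(selected) >= max_steps:
            reason = "max steps reached"
            break
        Usel = _orthobasis(Xall[:, selected]) if selected else np.empty((n, 0))
        Xrem = Xall[:, remaining]
        Xres = Xrem - Usel @ (Usel.T @ Xrem)
        norms = np.linalg.norm(Xres, axis=0)
        valid = norms > 1e-8 * max(np.linalg.norm(Xrem, axis=0).max(), 1.0)
        if not valid.any():
            reason = "remaining candidates collinear with selection"
            break
        U = Xres[:, valid] / norms[valid]
        gains = np.sum((U.T @ R) ** 2, axis=1) / ssy
        best_local = int(np.argmax(gains))
        best_j = [remaining[i] for i in np.nonzero(valid)[0]][best_local]
        gain = float(gains[best_local])
        new_r2 = cur_r2 + gain
        new_aic = _aic(ssy, new_r2, n, cur_rank + 1)
        new_adj = adjusted_r2(new_r2, n, cur_rank + 1)
        cur_adj = adjusted_r2(cur_r2, n, cur_rank)
        if new_adj <= cur_adj:
            reason = "no adjusted-R² improvement"
            break
        # permutation of current-model residuals; null statistic = max gain
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        exceed = 0
        thresh = gain * ssy - 1e-12
        for b in range(n_perm):
            Rp = R[perm_idx[b]]
            if np.max(np.sum((U.T @ Rp) ** 2, axis=1)) >= thresh:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
        if p > alpha:
            reason = f"best candidate p={p:.4g} > alpha={alpha}"
            break
        if require_aic and new_aic >= cur_aic:
            reason = "AIC did not decrease"
            break
        selected.append(best_j)
        cur_r2, cur_rank, cur_aic = new_r2, cur_rank + 1, new_aic
        Usel = _orthobasis(Xall[:, selected])
        R = Yc - Usel @ (Usel.T @ Yc)
        records.append(
            {
                "variable": names[best_j],
                "adj_r2": new_adj,
                "aic": new_aic,
                "p_value": p,
            }
        )
    return SelectionResult(
        selected=[names[j] for j in selected], records=records, stopping_reason=reason
    )


# ---------------------------------------------------------------------------
# partitioning

@dataclass
class PartitionResult:
    """Adjusted-R² fractions for one response.

    ``fractions`` holds soil-only, management-only, space-only, the pooled
    shared fraction (drawn as soil∩management; all overlap terms fold into
    it) and the residual.  ``unadjusted`` holds the same decomposition without
    the Ezekiel adjustment, whose parts sum to 1 exactly.
    """

    fractions: dict[str, float]
    unadjusted: dict[str, float]
    p_values: dict[str, float]
    selected: dict[str, list[str]]
    total_adj_r2: float
    flags: list[str] = field(default_factory=list)


def _perm_fraction_p(
    Yc: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p for the R² gain of full over reduced (residual shuffle)."""
    n = len(Yc)
    ssy = float(np.sum(Yc**2))
    U_full = _orthobasis(X_full - X_full.mean(axis=0)) if X_full.size else np.empty((n, 0))
    U_red = _orthobasis(X_reduced - X_reduced.mean(axis=0)) if X_reduced.size else np.empty((n, 0))
    r2_full = float(np.sum((U_full.T @ Yc) ** 2) / ssy)
    r2_red = float(np.sum((U_red.T @ Yc) ** 2) / ssy)
    stat = r2_full - r2_red
    fitted = U_red @ (U_red.T @ Yc)
    resid = Yc - fitted
    exceed = 0
    for _ in range(n_perm):
        Ystar = fitted + resid[rng.permutation(n)]
        Ystar = Ystar - Ystar.mean(axis=0)
        ss = float(np.sum(Ystar**2))
        s = (
            float(np.sum((U_full.T @ Ystar) ** 2) / ss)
            - float(np.sum((U_red.T @ Ystar) ** 2) / ss)
        )
        if s >= stat - 1e-12:
            exceed += 1
    return (1.0 + exceed) / (1.0 + n_perm)


def _partition(
    Y: np.ndarray,
    soil: np.ndarray,
    mgmt: np.ndarray,
    space: np.ndarray,
    n_perm: int,
    seed: int,
) -> PartitionResult:
    n = len(Y)
    Yc = Y - Y.mean(axis=0)
    flags: list[str] = []
    if soil.size == 0 and mgmt.size == 0 and space.size == 0:
        flags.append("all predictor blocks empty: fractions are trivially zero")
        zero = {
            "soil": 0.0,
            "management": 0.0,
            "space": 0.0,
            "shared_soil_management": 0.0,
            "residual": 1.0,
        }
        return PartitionResult(zero, dict(zero), {}, {}, 0.0, flags)

    def r2_of(*mats):
        mats = [m for m in mats if m.size]
        if not mats:
            return 0.0, 0
        return _r2(Yc, np.hstack(mats))

    r2_abc, m_abc = r2_of(soil, mgmt, space)
    r2_bc, m_bc = r2_of(mgmt, space)
    r2_ac, m_ac = r2_of(soil, space)
    r2_ab, m_ab = r2_of(soil, mgmt)

    adj = {
        "abc": adjusted_r2(r2_abc, n, m_abc),
        "bc": adjusted_r2(r2_bc, n, m_bc),
        "ac": adjusted_r2(r2_ac, n, m_ac),
        "ab": adjusted_r2(r2_ab, n, m_ab),
    }
    unique_soil = adj["abc"] - adj["bc"]
    unique_mgmt = adj["abc"] - adj["ac"]
    unique_space = adj["abc"] - adj["ab"]
    shared = adj["abc"] - unique_soil - unique_mgmt - unique_space
    fractions = {
        "soil": unique_soil,
        "management": unique_mgmt,
        "space": unique_space,
        "shared_soil_management": shared,
        "residual": 1.0 - adj["abc"],
    }
    u_soil = r2_abc - r2_bc
    u_mgmt = r2_abc - r2_ac
    u_space = r2_abc - r2_ab
    unadjusted = {
        "soil": u_soil,
        "management": u_mgmt,
        "space": u_space,
        "shared_soil_management": r2_abc - u_soil - u_mgmt - u_space,
        "residual": 1.0 - r2_abc,
    }
    flags.append(
        "three-way and pairwise overlap terms pooled into shared_soil_management"
    )

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    full = np.hstack([m for m in (soil, mgmt, space) if m.size])
    for key, block, others in (
        ("soil", soil, (mgmt, space)),
        ("management", mgmt, (soil, space)),
        ("space", space, (soil, mgmt)),
    ):
        if block.size == 0:
            continue
        reduced_mats = [m for m in others if m.size]
        reduced = np.hstack(reduced_mats) if reduced_mats else np.empty((n, 0))
        p_values[key] = _perm_fraction_p(Yc, full, reduced, n_perm, rng)
    return PartitionResult(
        fractions=fractions,
        unadjusted=unadjusted,
        p_values=p_values,
        selected={},
        total_adj_r2=adj["abc"],
        flags=flags,
    )


def partition_abundance(
    response,
    blocks: PredictorBlocks,
    soil_selected: list[str] | None = None,
    management_selected: list[str] | None = None,
    space_selected: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PartitionResult:
    """Three-block partial-regression partition of a (log-)abundance response.

    ``*_selected`` restrict each block to previously selected columns; ``None``
    uses the whole block.
    """
    Y = _as_matrix(response)
    soil = blocks.soil[soil_selected] if soil_selected is not None else blocks.soil
    mgmt = (
        blocks.management[management_selected]
        if management_selected is not None
        else blocks.management
    )
    space = blocks.space[space_selected] if space_selected is not None else blocks.space
    res = _partition(
        Y,
        soil.to_numpy(dtype=float),
        mgmt.to_numpy(dtype=float),
        space.to_numpy(dtype=float),
        n_perm,
        seed,
    )
    res.selected = {
        "soil": list(soil.columns),
        "management": list(mgmt.columns),
        "space": list(space.columns),
    }
    return res


def principal_coordinates(
    d: DistanceMatrix, neg_tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a dissimilarity matrix (Lingoes-corrected).

    Returns (coordinates on positive axes, eigenvalues).  When negative
    eigenvalues exceed ``neg_tol`` times the largest one, the Lingoes additive
    correction (add ``2c`` to all squared off-diagonal dissimilarities with
    ``c = -lambda_min``) is applied once; if negativity persists an error with
    the eigen-spectrum is raised.
    """
    D = d.values
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n

    def decompose(Dsq):
        G = -0.5 * J @ Dsq @ J
        vals, vecs = np.linalg.eigh(G)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = decompose(D**2)
    if vals[0] <= 0:
        raise DegenerateDataError("dissimilarity matrix has no positive eigenvalue")
    if vals[-1] < -neg_tol * vals[0]:
        c = -vals[-1]
        Dsq = D**2 + 2.0 * c
        np.fill_diagonal(Dsq, 0.0)
        vals, vecs = decompose(Dsq)
        if vals[-1] < -1e-6 * vals[0]:
            raise ValidationError(
                "negative eigenvalues persist after Lingoes correction; "
                f"spectrum head={vals[:3]}, tail={vals[-3:]}"
            )
    keep = vals > 1e-10 * vals[0]
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return coords, vals


def partition_community(
    d: DistanceMatrix,
    blocks: PredictorBlocks,
    soil_selected: list[str] | None = None,
    management_selected: list[str] | None = None,
    space_selected: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PartitionResult:
    """db-RDA partition of community dissimilarity among the three blocks.

    The dissimilarity matrix is converted to principal coordinates (with
    Lingoes correction when needed) and partitioned exactly like a
    multivariate abundance response; significance uses residualized
    permutation of the reduced model.
    """
    coords, _ = principal_coordinates(d)
    return partition_abundance(
        coords,
        blocks,
        soil_selected=soil_selected,
        management_selected=management_selected,
        space_selected=space_selected,
        n_perm=n_perm,
        seed=seed,
    )


def standardized_coefficients(response, X: pd.DataFrame) -> pd.DataFrame:
    """Standardized partial regression coefficients with marginal adj-R².

    Coefficients are reported on the standardized scale
    ``beta * sd(x) / sd(y)``; the marginal contribution of each variable is
    the adjusted-R² drop when it is removed from the full model (signed
    coefficients, leave-one-covariate-out contributions).
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if len(X) != n:
        raise ValidationError("predictor rows must match the response length")
    Xm = X.to_numpy(dtype=float)
    Xc = Xm - Xm.mean(axis=0)
    yc = y - y.mean()
    sy = y.std(ddof=1)
    if sy == 0:
        raise DegenerateDataError("response has zero variance")
    beta, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    flagged = rank < Xc.shape[1]
    if flagged:
        warnings.warn("standardized_coefficients: rank-deficient fit, coefficients flagged")
    sx = Xm.std(ddof=1, axis=0)
    std_coef = beta * sx / sy
    r2_full, m_full = _r2(yc[:, None], Xc)
    adj_full = adjusted_r2(r2_full, n, m_full)
    marginal = []
    for j in range(Xc.shape[1]):
        rest = np.delete(Xc, j, axis=1)
        r2_red, m_red = _r2(yc[:, None], rest)
        marginal.append(adj_full - adjusted_r2(r2_red, n, m_red))
    return pd.DataFrame(
        {
            "variable": list(X.columns),
            "coefficient": std_coef,
            "marginal_adj_r2": marginal,
            "flagged": flagged,
        }
    )


def log_relative_abundance(props: pd.DataFrame) -> pd.DataFrame:
    """Log-transform per-taxon relative abundances.

    Zeros are replaced by half the smallest positive value of that taxon
    (logged); taxa with no positive value raise.
    """
    out = props.astype(float).copy()
    for taxon in out.index:
        row = out.loc[taxon]
        pos = row[row > 0]
        if pos.empty:
            raise DegenerateDataError(f"taxon {taxon!r} has no positive abundance")
        if (row == 0).any():
            logger.info(
                "log_relative_abundance: %d zeros in %r replaced by %.3g",
                int((row == 0).sum()), taxon, pos.min() / 2.0,
            )
            out.loc[taxon] = row.replace(0.0, pos.min() / 2.0)
    return np.log(out)
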