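"""Community-level analysis: rarefaction, taxonomy aggregation, weighted
UniFrac, NMDS ordination, soil PCA and permutation-based vector fitting."""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateDataError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityTable",
    "DistanceMatrix",
    "OrdinationResult",
    "FittedVector",
    "rarefy_counts",
    "aggregate_taxonomy",
    "weighted_unifrac",
    "nmds",
    "pca_soil",
    "fit_vectors",
]

RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class CommunityTable:
    """Taxa-by-sites table of counts or proportions plus lineage strings."""

    data: pd.DataFrame  # index: taxon ids, columns: site ids
    lineages: pd.Series  # indexed by taxon id; semicolon-delimited ranks

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.lineages.index):
            self.lineages = self.lineages.reindex(self.data.index)
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("community table entries must be nonnegative")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def sites(self) -> list[str]:
        return list(self.data.columns)

    def to_proportions(self) -> "CommunityTable":
        totals = self.data.sum(axis=0)
        if (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise ValidationError(f"sites with zero total counts: {empty}")
        return CommunityTable(self.data / totals, self.lineages.copy())


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape must match id count")
        asym = np.abs(self.values - self.values.T)
        if asym.max(initial=0.0) > 1e-10:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"distance matrix asymmetric at ({self.ids[i]}, {self.ids[j]}): "
                f"{self.values[i, j]} != {self.values[j, i]}"
            )
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal must be zero")
        if self.values.min(initial=0.0) < 0:
            raise ValidationError("dissimilarities must be nonnegative")


@dataclass
class OrdinationResult:
    """Site scores on k axes plus method-specific diagnostics."""

    site_ids: list[str]
    scores: np.ndarray  # (n, k)
    method: str
    stress: float | None = None  # NMDS only
    eigenvalues: np.ndarray | None = None
    explained: np.ndarray | None = None  # proportions, nonincreasing
    loadings: pd.DataFrame | None = None  # PCA only

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.stress is not None and not 0.0 <= self.stress <= 1.0:
            raise ValidationError(f"NMDS stress must be in [0, 1], got {self.stress}")


@dataclass
class FittedVector:
    variable: str
    direction: np.ndarray  # unit-norm cosines on the ordination axes
    r2: float
    p_value: float
    retained: bool

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(self.direction), 1.0, atol=1e-8):
            raise ValidationError("direction must have unit norm")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValidationError(f"R^2 must be in [0, 1], got {self.r2}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError("p-value must be in (0, 1]")


def rarefy_counts(table: CommunityTable, depth: int, seed: int = 0) -> CommunityTable:
    """Subsample every site without replacement to exactly ``depth`` reads.

    Sites with fewer than ``depth`` total counts are dropped with a logged
    warning.  Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be > 0")
    counts = table.data.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValidationError("rarefaction requires integer counts")
    counts = counts.astype(np.int64)
    totals = counts.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sites, keep) if not k]
    if dropped:
        logger.warning("rarefy_counts: dropping %d sites below depth %d: %s",
                       len(dropped), depth, dropped)
        warnings.warn(f"rarefaction dropped {len(dropped)} sites below depth {depth}")
    rng = np.random.default_rng(seed)
    out = np.zeros((counts.shape[0], int(keep.sum())), dtype=np.int64)
    for jo, j in enumerate(np.nonzero(keep)[0]):
        if totals[j] == depth:
            out[:, jo] = counts[:, j]
        else:
            out[:, jo] = rng.multivariate_hypergeometric(counts[:, j], depth)
    data = pd.DataFrame(out, index=table.data.index,
                        columns=[s for s, k in zip(table.sites, keep) if k])
    return CommunityTable(data, table.lineages.copy())


def _lineage_group(lineage: str, rank: str) -> str:
    if not isinstance(lineage, str) or not lineage.strip():
        return "unclassified"
    parts = [p.strip() for p in lineage.split(";")]
    if rank == "phylum_with_proteobacteria_classes":
        if len(parts) < 2 or not parts[1]:
            return "unclassified"
        if parts[1] == "Proteobacteria":
            if len(parts) >= 3 and parts[2]:
                return parts[2]
            return "Proteobacteria;unclassified"
        return parts[1]
    try:
        idx = RANK_NAMES.index(rank)
    except ValueError:
        raise ValidationError(f"unknown rank {rank!r}") from None
    if len(parts) <= idx or not parts[idx]:
        return "unclassified"
    return parts[idx]


def aggregate_taxonomy(table: CommunityTable, rank: str = "phylum") -> CommunityTable:
    """Sum counts within lineage groups at the requested rank.

    ``rank="phylum_with_proteobacteria_classes"`` splits Proteobacteria into
    its classes while all other phyla stay whole; unparseable lineages pool
    into ``"unclassified"``.
    """
    if table.data.empty:
        raise ValidationError("cannot aggregate an empty community table")
    groups = table.lineages.map(lambda s: _lineage_group(s, rank))
    agg = table.data.groupby(groups.to_numpy()).sum()
    lineages = pd.Series(agg.index.to_list(), index=agg.index, name="lineage")
    return CommunityTable(agg, lineages)


def _branch_table(tree):
    """(branch length vector, branch x leaf incidence matrix, leaf names)."""
    leaves = [t for t in tree.tips()]
    names = [t.name for t in leaves]
    index = {id(t): i for i, t in enumerate(leaves)}
    rows, lengths = [], []
    for node in tree.postorder(include_self=False):
        length = node.length if node.length is not None else 0.0
        if length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
        mask = np.zeros(len(leaves), dtype=float)
        for tip in node.tips(include_self=True):
            mask[index[id(tip)]] = 1.0
        rows.append(mask)
        lengths.append(length)
    return np.asarray(lengths, float), np.asarray(rows), names


def weighted_unifrac(
    table: CommunityTable, tree, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac distances between every pair of sites.

    Raw distance sums ``b * |p_A - p_B|`` over branches, where ``p_S`` is the
    proportion of sample S descending from the branch; the normalized form
    divides by ``sum b * (p_A + p_B)`` and lies in [0, 1].
    """
    from skbio import TreeNode

    if isinstance(tree, str):
        tree = TreeNode.read(io.StringIO(tree))
    props = table.data.to_numpy(dtype=float)
    totals = props.sum(axis=0)
    if not np.allclose(totals, 1.0, atol=1e-9):
        props = props / totals  # accept counts; convert to proportions
    lengths, incidence, leaf_names = _branch_table(tree)
    missing = sorted(set(table.taxa) - set(leaf_names))
    if missing:
        raise SchemaError(f"table taxa missing from the tree: {missing}")
    order = [leaf_names.index(t) for t in table.taxa]
    P = incidence[:, order] @ props  # branch x site proportions
    B = P * lengths[:, None]
    raw = squareform(pdist(B.T, metric="cityblock"))
    if not normalized:
        return DistanceMatrix(table.sites, raw)
    t = lengths @ P  # per-site sum of b * p
    denom = t[:, None] + t[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, raw / denom, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sites, d)


def classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Principal-coordinates (Torgerson) configuration on k axes."""
    d = np.asarray(d, dtype=float)
    n = len(d)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, k))
    for j in range(min(k, n)):
        if vals[j] > 0:
            coords[:, j] = vecs[:, j] * np.sqrt(vals[j])
    return coords


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 300,
) -> OrdinationResult:
    """Nonmetric MDS minimising Kruskal stress-1 (monotone regression).

    One start from classical scaling plus ``restarts - 1`` random starts; the
    lowest-stress configuration wins.
    """
    from sklearn.manifold import smacof

    if k < 1:
        raise ValidationError("k must be >= 1")
    n = len(d.ids)
    if n < k + 2:
        raise ValidationError(f"need n >= k + 2 sites, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    dd = d.values
    best = None
    trace = []
    for r in range(max(restarts, 1)):
        init = classical_scaling(dd, k) if r == 0 else rng.standard_normal((n, k))
        try:
            coords, stress = smacof(
                dd,
                metric=False,
                n_components=k,
                init=init,
                n_init=1,
                max_iter=max_iter,
                eps=1e-8,
                normalized_stress=True,
                random_state=0,
            )
        except Exception as exc:
            trace.append(f"restart {r}: {exc}")
            continue
        trace.append(f"restart {r}: stress={stress:.6f}")
        if best is None or stress < best[1]:
            best = (coords, float(stress))
    if best is None:
        raise ValidationError("NMDS failed in every restart: " + "; ".join(trace))
    coords, stress = best
    return OrdinationResult(site_ids=list(d.ids), scores=coords, method="nmds",
                            stress=min(max(stress, 0.0), 1.0))


def pca_soil(site_table: pd.DataFrame, variables: list[str]) -> OrdinationResult:
    """PCA on standardized soil variables (complete cases only)."""
    if len(variables) < 2:
        raise ValidationError("PCA needs at least 2 variables")
    missing = sorted(set(variables) - set(site_table.columns))
    if missing:
        raise SchemaError(f"variables missing from site table: {missing}")
    X = site_table[variables].astype(float)
    complete = X.notna().all(axis=1)
    if not complete.all():
        logger.warning("pca_soil: dropping %d incomplete rows", int((~complete).sum()))
    X = X[complete]
    sds = X.std(ddof=1)
    zero = list(sds.index[sds == 0])
    if zero:
        warnings.warn(f"pca_soil: dropping zero-variance variables {zero}")
        X = X.drop(columns=zero)
        if X.shape[1] < 2:
            raise DegenerateDataError("fewer than 2 variables after pruning")
    Z = (X - X.mean()) / X.std(ddof=1)
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    eigvals = s**2 / (len(Z) - 1)
    scores = U * s
    ids = list(site_table.loc[complete, "site_id"].astype(str)) if "site_id" in site_table else [
        str(i) for i in X.index
    ]
    loadings = pd.DataFrame(
        Vt.T, index=X.columns, columns=[f"PC{i + 1}" for i in range(len(s))]
    )
    return OrdinationResult(
        site_ids=ids,
        scores=scores,
        method="pca",
        eigenvalues=eigvals,
        explained=eigvals / eigvals.sum(),
        loadings=loadings,
    )


def fit_vectors(
    ordination: OrdinationResult,
    variables: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    r2_min: float = 0.20,
    alpha: float = 0.001,
) -> list[FittedVector]:
    """Fit environmental vectors onto ordination axes with permutation tests.

    Direction = unit-norm regression of the variable on the score matrix;
    R^2 = squared multiple correlation; p-values use the add-one rule
    ``(1 + #{permuted R^2 >= observed}) / (1 + n_perm)``.  A vector is
    retained when R^2 >= ``r2_min`` and p <= ``alpha``.
    """
    if n_perm < 99:
        raise ValidationError("need at least 99 permutations")
    S = ordination.scores - ordination.scores.mean(axis=0)
    n = len(S)
    if len(variables) != n:
        raise ValidationError("variables must align with ordination sites")
    pinv = np.linalg.pinv(S)
    rng = np.random.default_rng(seed)
    out: list[FittedVector] = []
    for name in variables.columns:
        y = variables[name].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"fit_vectors: skipping constant variable {name!r}")
            continue
        yc = y - y.mean()
        ssy = yc @ yc
        coef = pinv @ yc
        fitted = S @ coef
        r2 = float(fitted @ fitted / ssy)
        # batched permutations: columns are permuted copies of yc
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        Yp = yc[perm_idx].T  # n x n_perm
        Fp = S @ (pinv @ Yp)
        r2p = np.einsum("ij,ij->j", Fp, Fp) / ssy
        p = (1.0 + np.count_nonzero(r2p >= r2 - 1e-12)) / (1.0 + n_perm)
        direction = coef / np.linalg.norm(coef)
        out.append(
            FittedVector(
                variable=name,
                direction=direction,
                r2=min(r2, 1.0),
                p_value=p,
                retained=bool(r2 >= r2_min and p <= alpha),
            )
        )
    return out
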