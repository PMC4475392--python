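"""Synthetic landscape generator.

Produces sampling designs (regular grid plus short-distance infill sites),
Matérn-correlated Gaussian soil fields with target cross-correlations,
spatially contiguous land-management clusters with exact per-cluster counts,
and compositional taxon count tables driven by soil, management and residual
spatial structure through a logistic-normal-multinomial forward model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon

from .community import CommunityTable
from .errors import (
    ConfigurationError,
    DecompositionError,
    GeometryError,
    SchemaError,
    ValidationError,
)
from .geostat.kriging import covariance_matrix
from .geostat.variogram import VariogramModel

__all__ = [
    "SamplingDesign",
    "FieldSpec",
    "TaxonSpec",
    "CommunitySpec",
    "rectangle_for_grid",
    "generate_sampling_design",
    "simulate_gaussian_field",
    "attach_soil_and_management",
    "simulate_community",
    "random_coalescent_tree",
]


@dataclass
class SamplingDesign:
    """Site ids and coordinates for a grid-plus-infill sampling layout."""

    site_ids: list[str]
    xy: np.ndarray  # (n, 2) metres
    is_grid: np.ndarray  # bool mask, True for lattice sites
    grid_spacing: float
    polygon: Polygon

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.is_grid = np.asarray(self.is_grid, dtype=bool)
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("site ids must be unique")
        if len(self.site_ids) != len(self.xy) or len(self.xy) != len(self.is_grid):
            raise ValidationError("ids, coordinates and grid mask must align")
        inside = shapely.contains_xy(
            self.polygon.buffer(1e-6), self.xy[:, 0], self.xy[:, 1]
        )
        if not np.all(inside):
            raise GeometryError("all sites must lie inside the bounding polygon")

    def __len__(self) -> int:
        return len(self.site_ids)


@dataclass
class FieldSpec:
    """Generator-side description of one Gaussian soil field."""

    name: str
    variogram: VariogramModel
    mean: float = 0.0
    cross_correlations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for partner, r in self.cross_correlations.items():
            if not -1.0 <= r <= 1.0:
                raise ValidationError(
                    f"target correlation with {partner!r} must be in [-1, 1], got {r}"
                )


@dataclass
class TaxonSpec:
    """Effect structure for one taxon in the compositional forward model."""

    name: str
    lineage: str
    baseline_logit: float = 0.0
    env_coefficients: dict[str, float] = field(default_factory=dict)
    cluster_offsets: dict[str, float] = field(default_factory=dict)
    spatial_variogram: VariogramModel | None = None
    overdispersion: float = 0.0


@dataclass
class CommunitySpec:
    taxa: list[TaxonSpec]
    library_size: int = 10_800

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValidationError("library_size must be > 0")
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            raise ValidationError("taxon names must be unique")


def rectangle_for_grid(spacing: float, n_grid: int, margin: float = 0.5) -> Polygon:
    """Smallest near-square rectangle whose lattice holds >= n_grid nodes."""
    ncols = math.ceil(math.sqrt(n_grid))
    nrows = math.ceil(n_grid / ncols)
    m = margin * spacing
    return Polygon(
        [
            (-m, -m),
            ((ncols - 1) * spacing + m, -m),
            ((ncols - 1) * spacing + m, (nrows - 1) * spacing + m),
            (-m, (nrows - 1) * spacing + m),
        ]
    )


def generate_sampling_design(
    spacing: float,
    n_grid: int,
    n_infill: int,
    polygon: Polygon | None = None,
    seed: int = 0,
) -> SamplingDesign:
    """Lattice sampling design plus infill sites inside lattice cells.

    Grid sites are the first ``n_grid`` lattice nodes inside ``polygon`` in
    row-major order.  Each infill site is offset from a randomly chosen grid
    site by less than half the spacing (times sqrt 2), so its nearest grid
    site is closer than one spacing interval.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be > 0")
    if polygon is None:
        polygon = rectangle_for_grid(spacing, n_grid)
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = polygon.bounds
    i0, i1 = math.floor(minx / spacing), math.ceil(maxx / spacing)
    j0, j1 = math.floor(miny / spacing), math.ceil(maxy / spacing)
    jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1), indexing="ij")
    nodes = np.column_stack([ii.ravel() * spacing, jj.ravel() * spacing])
    inside = shapely.contains_xy(polygon.buffer(1e-9), nodes[:, 0], nodes[:, 1])
    nodes = nodes[inside]  # row-major: y-major then x from the meshgrid ordering
    if len(nodes) < n_grid:
        raise GeometryError(
            f"polygon holds only {len(nodes)} lattice nodes at spacing {spacing}; "
            f"{n_grid} grid sites requested"
        )
    grid_xy = nodes[:n_grid]

    infill_xy = np.empty((n_infill, 0 if n_infill == 0 else 2)).reshape(n_infill, 2)
    if n_infill > 0:
        hosts = rng.choice(
            n_grid, size=n_infill, replace=n_infill > n_grid
        )
        for k, h in enumerate(hosts):
            offset_scale = 0.45 * spacing
            for _ in range(200):
                cand = grid_xy[h] + rng.uniform(-offset_scale, offset_scale, size=2)
                if shapely.contains_xy(polygon, cand[0], cand[1]):
                    infill_xy[k] = cand
                    break
                offset_scale *= 0.8  # shrink toward the host node until inside
            else:  # pragma: no cover - host is inside, so shrinking terminates
                infill_xy[k] = grid_xy[h]

    xy = np.vstack([grid_xy, infill_xy])
    ids = [f"g{i + 1:03d}" for i in range(n_grid)] + [
        f"i{i + 1:03d}" for i in range(n_infill)
    ]
    is_grid = np.array([True] * n_grid + [False] * n_infill)
    return SamplingDesign(ids, xy, is_grid, spacing, polygon)


def _unit_field_cholesky(xy: np.ndarray, model: VariogramModel) -> np.ndarray:
    """Cholesky factor of the unit-variance correlation implied by the model."""
    C = covariance_matrix(xy, model) / model.sill
    C[np.diag_indices(len(xy))] += 1e-10
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise DecompositionError(
            "field covariance not positive definite for parameters "
            f"(c0={model.nugget}, c1={model.partial_sill}, a={model.range_}, "
            f"v={model.smoothness})"
        ) from exc


def simulate_gaussian_field(
    design: SamplingDesign | np.ndarray,
    spec: FieldSpec,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One realization of a stationary Gaussian field at the design sites.

    Covariance is ``c1*rho(h) + c0*1{h=0}`` from the spec's variogram; the
    result is deterministic given ``seed``.
    """
    xy = design.xy if isinstance(design, SamplingDesign) else np.asarray(design, float)
    if rng is None:
        rng = np.random.default_rng(seed)
    m = spec.variogram
    L = _unit_field_cholesky(xy, m) * math.sqrt(m.sill)
    return spec.mean + L @ rng.standard_normal(len(xy))


def _correlation_matrix(field_specs: list[FieldSpec]) -> np.ndarray:
    names = [f.name for f in field_specs]
    k = len(names)
    R = np.eye(k)
    for i, f in enumerate(field_specs):
        for partner, r in f.cross_correlations.items():
            if partner not in names:
                raise ConfigurationError(
                    f"field {f.name!r} references unknown partner {partner!r}"
                )
            j = names.index(partner)
            if R[i, j] not in (0.0, r):
                raise ConfigurationError(
                    f"conflicting target correlations for ({f.name}, {partner})"
                )
            R[i, j] = R[j, i] = r
    return R


def _grow_clusters(
    xy: np.ndarray, counts: dict[str, int], rng: np.random.Generator
) -> np.ndarray:
    """Seeded Voronoi-style growth to spatially contiguous clusters.

    Each label claims, round-robin, the unassigned site nearest to its seed
    point until its quota is filled; ties break on site index.
    """
    n = len(xy)
    labels = list(counts)
    total = sum(counts.values())
    if total != n:
        raise ConfigurationError(
            f"cluster counts sum to {total} but the design has {n} sites"
        )
    seeds = rng.choice(n, size=len(labels), replace=False)
    dist = cdist(xy[seeds], xy)  # label x site
    assigned = np.full(n, -1, dtype=int)
    remaining = {lab: counts[lab] for lab in labels}
    while any(remaining.values()):
        for li, lab in enumerate(labels):
            if remaining[lab] == 0:
                continue
            free = np.nonzero(assigned < 0)[0]
            # stable nearest: distance first, site index breaks ties
            pick = free[np.lexsort((free, dist[li, free]))[0]]
            assigned[pick] = li
            remaining[lab] -= 1
    return np.array([labels[a] for a in assigned])


def attach_soil_and_management(
    design: SamplingDesign,
    field_specs: list[FieldSpec],
    cluster_counts: dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Site table with correlated soil fields and exact cluster counts.

    Cross-correlations are imposed by Cholesky mixing of independent
    unit-variance fields (exact in expectation when partners share spatial
    structure); management labels are grown as contiguous patches.
    """
    rng = np.random.default_rng(seed)
    n = len(design)
    R = _correlation_matrix(field_specs)
    try:
        Lmix = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(
            "requested cross-correlation matrix is not positive definite"
        ) from exc
    Z = np.column_stack(
        [
            _unit_field_cholesky(design.xy, f.variogram) @ rng.standard_normal(n)
            for f in field_specs
        ]
    )
    X = Z @ Lmix.T
    data = {"site_id": design.site_ids, "x": design.xy[:, 0], "y": design.xy[:, 1]}
    for i, f in enumerate(field_specs):
        data[f.name] = f.mean + math.sqrt(f.variogram.sill) * X[:, i]
    df = pd.DataFrame(data)
    df["management"] = _grow_clusters(design.xy, cluster_counts, rng)
    return df


def simulate_community(
    site_table: pd.DataFrame,
    spec: CommunitySpec,
    seed: int = 0,
) -> CommunityTable:
    """Multinomial taxon counts from a softmax of linear soil/management logits.

    Per-site logit of taxon t: baseline + sum(coef * standardized soil column)
    + management offset + spatial Gaussian residual + iid overdispersion.
    """
    rng = np.random.default_rng(seed)
    n = len(site_table)
    missing = sorted(
        {c for t in spec.taxa for c in t.env_coefficients} - set(site_table.columns)
    )
    if missing:
        raise SchemaError(f"soil columns missing from site table: {missing}")
    xy = site_table[["x", "y"]].to_numpy(dtype=float)
    mgmt = site_table["management"].astype(str).to_numpy() if "management" in site_table else None
    logits = np.zeros((len(spec.taxa), n))
    for ti, taxon in enumerate(spec.taxa):
        row = np.full(n, taxon.baseline_logit, dtype=float)
        for col, coef in taxon.env_coefficients.items():
            v = site_table[col].to_numpy(dtype=float)
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValidationError(f"soil column {col!r} is constant")
            row += coef * (v - v.mean()) / sd
        if taxon.cluster_offsets:
            if mgmt is None:
                raise SchemaError("cluster_offsets given but site table has no 'management'")
            row += np.array([taxon.cluster_offsets.get(m, 0.0) for m in mgmt])
        if taxon.spatial_variogram is not None and taxon.spatial_variogram.sill > 0:
            m = taxon.spatial_variogram
            L = _unit_field_cholesky(xy, m) * math.sqrt(m.sill)
            row += L @ rng.standard_normal(n)
        if taxon.overdispersion > 0:
            row += taxon.overdispersion * rng.standard_normal(n)
        logits[ti] = row
    logits -= logits.max(axis=0, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=0, keepdims=True)
    counts = np.column_stack(
        [rng.multinomial(spec.library_size, probs[:, j]) for j in range(n)]
    )
    data = pd.DataFrame(
        counts,
        index=[t.name for t in spec.taxa],
        columns=[str(s) for s in site_table["site_id"]],
    )
    lineages = pd.Series(
        {t.name: t.lineage for t in spec.taxa}, name="lineage"
    ).reindex(data.index)
    return CommunityTable(data=data, lineages=lineages)


def random_coalescent_tree(names: list[str], seed: int = 0, rate: float = 1.0) -> str:
    """Newick string for a random coalescent-style tree over ``names``.

    Lineages merge pairwise at exponentially distributed waiting times; branch
    lengths are differences of merge heights (ultrametric).
    """
    if len(names) < 2:
        raise ValidationError("need at least two leaf names")
    rng = np.random.default_rng(seed)
    nodes = [(str(nm), 0.0) for nm in names]  # (newick fragment, height)
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(rate / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (si, hi), (sj, hj) = nodes[i], nodes[j]
        frag = f"({si}:{height - hi:.6f},{sj}:{height - hj:.6f})"
        nodes = [nodes[m] for m in range(k) if m not in (i, j)] + [(frag, height)]
    return nodes[0][0] + ";"
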