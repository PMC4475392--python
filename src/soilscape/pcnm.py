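"""PCNM spatial eigenvectors (principal coordinates of a neighbour matrix).

The inter-site distance matrix is truncated (distances beyond the threshold
replaced by four times the threshold), double-centred as in principal
coordinates analysis, and eigendecomposed.  Eigenvectors with positive
eigenvalues become multi-scale spatial predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .errors import GeometryError, ValidationError

__all__ = ["SpatialEigenbasis", "build_pcnm", "mst_longest_edge"]


@dataclass
class SpatialEigenbasis:
    truncation: float
    eigenvalues: np.ndarray  # all retained, sorted descending
    vectors: np.ndarray  # (n sites, k) orthonormal, centred, unit norm
    tolerance: float

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValidationError("eigenvalues must be sorted descending")

    @property
    def names(self) -> list[str]:
        return [f"PCNM{i + 1}" for i in range(self.vectors.shape[1])]


def mst_longest_edge(site_xy: np.ndarray) -> float:
    """Longest edge of the minimum spanning tree over the sites."""
    D = squareform(pdist(np.asarray(site_xy, dtype=float)))
    mst = minimum_spanning_tree(D)
    return float(mst.data.max())


def build_pcnm(
    site_xy: np.ndarray,
    truncation: float | str = "auto",
    tolerance: float = 1e-8,
) -> SpatialEigenbasis:
    """Spatial eigenvectors from a truncated, double-centred distance matrix.

    ``truncation="auto"`` uses the longest minimum-spanning-tree edge (the
    classic rule, which keeps the neighbour graph connected).  Eigenvectors
    with eigenvalue > ``tolerance`` times the largest eigenvalue are kept,
    scaled to unit norm, with the sign fixed so the first nonzero loading of
    each vector is positive.
    """
    xy = np.asarray(site_xy, dtype=float)
    if len(xy) < 3:
        raise ValidationError("PCNM needs at least 3 sites")
    D = squareform(pdist(xy))
    if D.max() == 0:
        raise GeometryError("all sites coincide: PCNM geometry is degenerate")
    if truncation == "auto":
        threshold = mst_longest_edge(xy)
    else:
        threshold = float(truncation)
        if threshold <= 0:
            raise ValidationError("truncation threshold must be > 0")
    Dt = np.where(D > threshold, 4.0 * threshold, D)
    np.fill_diagonal(Dt, 0.0)
    n = len(xy)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (Dt**2) @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    cut = tolerance * vals[0]
    keep = vals > cut
    vals, vecs = vals[keep], vecs[:, keep]
    # eigh returns orthonormal columns; fix the sign convention
    for j in range(vecs.shape[1]):
        col = vecs[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            vecs[:, j] = -col
    return SpatialEigenbasis(
        truncation=threshold, eigenvalues=vals, vectors=vecs, tolerance=cut
    )
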