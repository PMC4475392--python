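"""File readers and writers for the documented plain-text dialects.

Site tables and PCNM scores are comma-separated; community tables and
distance matrices are tab-separated; trees are Newick.  Every writer/reader
pair round-trips losslessly.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import CommunityTable, DistanceMatrix
from .errors import FormatError

__all__ = [
    "read_site_table",
    "write_site_table",
    "read_community_table",
    "write_community_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_pcnm_scores",
    "write_pcnm_scores",
    "read_tree_newick",
    "write_surface",
    "read_config",
    "write_config",
    "write_json",
]


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "site_id" not in df.columns or "x" not in df.columns or "y" not in df.columns:
        raise FormatError(f"{path}: site table must have site_id, x, y columns")
    df["site_id"] = df["site_id"].astype(str)
    return df


def write_site_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_community_table(path) -> CommunityTable:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3 or df.columns[0] != "taxon" or df.columns[1] != "lineage":
        raise FormatError(
            f"{path}: community table must start with 'taxon' and 'lineage' columns"
        )
    df = df.set_index("taxon")
    lineages = df.pop("lineage").astype(str)
    return CommunityTable(df.astype(float), lineages)


def write_community_table(table: CommunityTable, path) -> None:
    out = table.data.copy()
    out.insert(0, "lineage", table.lineages)
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise FormatError(f"{path}: distance matrix row and column ids differ")
    values = df.to_numpy(dtype=float)
    asym = np.abs(values - values.T)
    if asym.max(initial=0.0) > 1e-10:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise FormatError(
            f"{path}: asymmetric at ({ids[i]}, {ids[j]}): "
            f"{values[i, j]} != {values[j, i]}"
        )
    return DistanceMatrix(ids, values)


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    pd.DataFrame(d.values, index=d.ids, columns=d.ids).to_csv(path, sep="\t")


def read_pcnm_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise FormatError(f"{path}: PCNM scores must carry a site_id column")
    df["site_id"] = df["site_id"].astype(str)
    return df


def write_pcnm_scores(site_ids, vectors: np.ndarray, path) -> None:
    cols = [f"PCNM{i + 1}" for i in range(vectors.shape[1])]
    out = pd.DataFrame(vectors, columns=cols)
    out.insert(0, "site_id", [str(s) for s in site_ids])
    out.to_csv(path, index=False)


def read_tree_newick(path_or_text, require_branch_lengths: bool = True):
    """Parse a Newick tree; optionally demand branch lengths (UniFrac needs them)."""
    from skbio import TreeNode

    text = path_or_text
    try:
        is_file = Path(str(path_or_text)).exists()
    except OSError:  # raw newick text can exceed filename limits
        is_file = False
    if isinstance(path_or_text, (str, Path)) and is_file:
        text = Path(path_or_text).read_text()
    tree = TreeNode.read(_io.StringIO(str(text)))
    if require_branch_lengths:
        missing = [
            n.name for n in tree.postorder(include_self=False) if n.length is None
        ]
        if missing:
            raise FormatError(
                "tree lacks branch lengths (required for UniFrac) at nodes: "
                f"{missing[:5]}"
            )
    return tree


def write_surface(surface, path) -> None:
    """Kriging surface as long-format CSV: x, y, prediction, kriging_variance."""
    pd.DataFrame(
        {
            "x": surface.grid_xy[:, 0],
            "y": surface.grid_xy[:, 1],
            "prediction": surface.predictions,
            "kriging_variance": surface.variances,
        }
    ).to_csv(path, index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
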