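"""End-to-end pipeline: simulate -> ordinate -> krige -> validate -> pcnm -> varpart.

Every stage reads and writes serialized artifacts in the run directory, so
any stage can be re-run from its upstream files.  A single master seed
deterministically derives one child seed per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community as comm
from . import io as sio
from . import synthetic as syn
from ._seeds import child_seed
from .errors import ConfigurationError
from .geostat import (
    VariogramModel,
    effective_range,
    empirical_variogram,
    fit_variogram,
    loo_cross_validate,
    normal_scores_transform,
    ordinary_kriging,
    sspe_diagnostics,
)
from .pcnm import build_pcnm
from .varpart import (
    forward_select,
    log_relative_abundance,
    partition_abundance,
    partition_community,
    prepare_blocks,
    standardized_coefficients,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "default_scenario"]

STAGES = ("simulate", "ordinate", "krige", "validate", "pcnm", "varpart")

# Six land-management intensity levels; counts chosen to fill the default
# 278-site design (the largest, most intensive cluster absorbs the slack).
DEFAULT_CLUSTER_COUNTS = {
    "Forest": 44,
    "PerennialCover": 7,
    "CatchCrop": 22,
    "MinimumTillage": 57,
    "MechanicalHoeing": 33,
    "ConventionalTillage": 115,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with the package-wide defaults."""

    seed: int
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    paths: dict = field(default_factory=dict)  # optional external inputs
    # sampling / simulation
    grid_spacing: float = 215.0
    n_grid: int = 248
    n_infill: int = 30
    cluster_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLUSTER_COUNTS))
    library_size: int = 10_800
    # community stage
    rarefaction_depth: int = 10_800
    nmds_axes: int = 2
    nmds_restarts: int = 4
    permutations: int = 999
    vector_r2_min: float = 0.20
    # geostatistics
    fit_method: str = "wls"
    krige_variables: tuple = ("NMDS1", "NMDS2", "pH")
    grid_step: float = 100.0
    sspe_simulations: int = 1000
    # variance partitioning
    alpha: float = 0.001
    corr_threshold: float = 0.9
    pcnm_truncation: str | float = "auto"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages in config: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        if self.seed is None:
            raise ConfigurationError("a master seed is mandatory")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ConfigurationError("config must set a master seed")
        d = dict(d)
        if "krige_variables" in d:
            d["krige_variables"] = tuple(d["krige_variables"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["krige_variables"] = list(d["krige_variables"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# default synthetic scenario

_TAXA = [
    # name, lineage, baseline, env coefficients, cluster offsets, range
    ("Alphaproteobacteria", "Bacteria;Proteobacteria;Alphaproteobacteria", 1.8,
     {"pH": 0.8}, {"Forest": -0.5}, 500.0),
    ("Betaproteobacteria", "Bacteria;Proteobacteria;Betaproteobacteria", 1.2,
     {"organic_carbon": 0.6, "clay": -0.3}, {}, 600.0),
    ("Gammaproteobacteria", "Bacteria;Proteobacteria;Gammaproteobacteria", 1.0,
     {}, {}, 0.0),
    ("Deltaproteobacteria", "Bacteria;Proteobacteria;Deltaproteobacteria", 1.1,
     {}, {"ConventionalTillage": -0.4, "Forest": 0.3}, 700.0),
    ("Acidobacteria", "Bacteria;Acidobacteria", 1.5, {"pH": -0.4}, {}, 0.0),
    ("Actinobacteria", "Bacteria;Actinobacteria", 1.7, {"caco3": 0.3}, {}, 700.0),
    ("Bacteroidetes", "Bacteria;Bacteroidetes", 0.9, {},
     {"ConventionalTillage": 0.5, "Forest": -0.4}, 500.0),
    ("Planctomycetes", "Bacteria;Planctomycetes", 0.8, {"pH": 0.7},
     {"ConventionalTillage": -0.3}, 700.0),
    ("Verrucomicrobia", "Bacteria;Verrucomicrobia", 0.6, {}, {"Forest": 0.4}, 1000.0),
    ("Gemmatimonadetes", "Bacteria;Gemmatimonadetes", 0.3,
     {"clay": 0.3}, {"ConventionalTillage": -0.2}, 600.0),
    ("Chlorobi", "Bacteria;Chlorobi", -0.2, {"organic_carbon": 0.8}, {}, 700.0),
    ("Firmicutes", "Bacteria;Firmicutes", 0.4, {"caco3": 0.4}, {}, 1000.0),
    ("Nitrospirae", "Bacteria;Nitrospirae", 0.0, {}, {"CatchCrop": 0.5}, 500.0),
    ("Fibrobacteres", "Bacteria;Fibrobacteres", -0.8, {},
     {"ConventionalTillage": 0.5, "Forest": -0.5}, 600.0),
    ("Armatimonadetes", "Bacteria;Armatimonadetes", -0.9, {},
     {"ConventionalTillage": 0.3}, 600.0),
    ("Elusimicrobia", "Bacteria;Elusimicrobia", -1.0, {"sand": 0.3}, {}, 1000.0),
    ("Thaumarchaeota", "Archaea;Thaumarchaeota", -0.5, {},
     {"ConventionalTillage": 0.4}, 1000.0),
    ("Crenarchaeota", "Archaea;Crenarchaeota", -1.1, {},
     {"ConventionalTillage": 0.3}, 600.0),
    ("Acidobacteria-Gp4", "Bacteria;Acidobacteria-Gp4", -0.3, {"pH": 0.5}, {}, 500.0),
]


def _soil_field_specs() -> list[syn.FieldSpec]:
    def vg(sill, rng_m):
        return VariogramModel(0.1 * sill, 0.9 * sill, rng_m, 0.5)

    return [
        syn.FieldSpec("clay", vg(60.0, 250.0), mean=34.0),
        syn.FieldSpec("sand", vg(20.0, 250.0), mean=10.0),
        syn.FieldSpec("pH", vg(0.25, 300.0), mean=7.7),
        syn.FieldSpec("organic_carbon", vg(40.0, 250.0), mean=22.0),
        syn.FieldSpec(
            "total_nitrogen", vg(0.3, 250.0), mean=1.9,
            cross_correlations={"organic_carbon": 0.92},
        ),
        syn.FieldSpec("caco3", vg(12.0, 300.0), mean=6.0),
    ]


def default_scenario(config: PipelineConfig, seed: int):
    """Design, site table (8 soil properties), community table and tree."""
    design = syn.generate_sampling_design(
        config.grid_spacing, config.n_grid, config.n_infill, seed=seed
    )
    sites = syn.attach_soil_and_management(
        design, _soil_field_specs(), config.cluster_counts, seed=seed + 1
    )
    # closure and stoichiometry columns mirror a full physicochemical panel
    sites.insert(5, "silt", 100.0 - sites["clay"] - sites["sand"])
    sites["cn_ratio"] = sites["organic_carbon"] / sites["total_nitrogen"].clip(lower=0.5)
    taxa = [
        syn.TaxonSpec(
            name=name,
            lineage=lineage,
            baseline_logit=base,
            env_coefficients=env,
            cluster_offsets=off,
            spatial_variogram=(
                VariogramModel(0.02, 0.08, rng_m, 0.5) if rng_m > 0 else None
            ),
            overdispersion=0.1,
        )
        for name, lineage, base, env, off, rng_m in _TAXA
    ]
    spec = syn.CommunitySpec(taxa=taxa, library_size=config.library_size)
    table = syn.simulate_community(sites, spec, seed=seed + 2)
    tree = syn.random_coalescent_tree([t.name for t in taxa], seed=seed + 3)
    return design, sites, table, tree


# ---------------------------------------------------------------------------
# stage runner

def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in dependency order; return the summary.

    Artifacts land in ``outdir``; the summary (also written as
    ``summary.json``) records per-stage key statistics, the config hash and
    every derived seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stages": {},
    }
    sio.write_config(config.to_dict(), out / "config.yaml")

    paths = {
        "sites": out / "sites.csv",
        "community": out / "community.tsv",
        "tree": out / "tree.nwk",
        "distance": out / "unifrac.tsv",
        "nmds": out / "nmds_scores.csv",
        "pcnm": out / "pcnm.csv",
    }
    for key, p in config.paths.items():
        paths[key] = Path(p)

    if config.stages.get("simulate"):
        seed = child_seed(config.seed, "simulate")
        design, sites, table, tree = default_scenario(config, seed)
        sio.write_site_table(sites, paths["sites"])
        sio.write_community_table(table, paths["community"])
        Path(paths["tree"]).write_text(tree + "\n")
        summary["stages"]["simulate"] = {
            "seed": seed,
            "n_sites": len(design),
            "n_grid": int(design.is_grid.sum()),
            "n_infill": int((~design.is_grid).sum()),
            "n_taxa": len(table.taxa),
            "cluster_counts": sites["management"].value_counts().to_dict(),
        }

    sites = sio.read_site_table(paths["sites"]) if paths["sites"].exists() else None
    soil_vars = (
        [c for c in sites.columns if c not in ("site_id", "x", "y", "management")]
        if sites is not None
        else []
    )

    if config.stages.get("ordinate"):
        seed = child_seed(config.seed, "ordinate")
        table = sio.read_community_table(paths["community"])
        tree = sio.read_tree_newick(paths["tree"])
        if config.rarefaction_depth:
            table = comm.rarefy_counts(table, config.rarefaction_depth, seed=seed)
        props = table.to_proportions()
        dmat = comm.weighted_unifrac(props, tree)
        sio.write_distance_matrix(dmat, paths["distance"])
        ordn = comm.nmds(
            dmat, k=config.nmds_axes, restarts=config.nmds_restarts, seed=seed + 1
        )
        nmds_df = pd.DataFrame(
            ordn.scores,
            columns=[f"NMDS{i + 1}" for i in range(config.nmds_axes)],
        )
        nmds_df.insert(0, "site_id", ordn.site_ids)
        nmds_df.to_csv(paths["nmds"], index=False)
        pca = comm.pca_soil(sites, soil_vars)
        pca_df = pd.DataFrame(
            pca.scores[:, :3], columns=["PC1", "PC2", "PC3"]
        )
        pca_df.insert(0, "site_id", pca.site_ids)
        pca_df.to_csv(out / "pca_scores.csv", index=False)
        variables = sites[soil_vars].copy()
        rel = props.data.T
        rel.index = props.sites
        variables = pd.concat(
            [variables.set_index(sites["site_id"]), rel], axis=1
        ).reset_index(drop=True)
        vectors = comm.fit_vectors(
            ordn,
            variables,
            n_perm=config.permutations,
            seed=seed + 2,
            r2_min=config.vector_r2_min,
            alpha=config.alpha,
        )
        vec_df = pd.DataFrame(
            [
                {
                    "variable": v.variable,
                    **{f"axis{i + 1}": c for i, c in enumerate(v.direction)},
                    "r2": v.r2,
                    "p_value": v.p_value,
                    "retained": v.retained,
                }
                for v in vectors
            ]
        )
        vec_df.to_csv(out / "vectors.csv", index=False)
        summary["stages"]["ordinate"] = {
            "seed": seed,
            "nmds_stress": ordn.stress,
            "pca_explained": [round(float(e), 6) for e in pca.explained[:3]],
            "n_vectors_retained": int(vec_df["retained"].sum()) if len(vec_df) else 0,
        }

    if config.stages.get("krige"):
        seed = child_seed(config.seed, "krige")
        nmds_df = (
            pd.read_csv(paths["nmds"]) if Path(paths["nmds"]).exists() else None
        )
        xy = sites[["x", "y"]].to_numpy(dtype=float)
        gx = np.arange(xy[:, 0].min(), xy[:, 0].max() + config.grid_step, config.grid_step)
        gy = np.arange(xy[:, 1].min(), xy[:, 1].max() + config.grid_step, config.grid_step)
        GX, GY = np.meshgrid(gx, gy)
        grid = np.column_stack([GX.ravel(), GY.ravel()])
        stage = {"seed": seed, "variables": {}}
        for var in config.krige_variables:
            if var in sites.columns:
                values = sites[var].to_numpy(dtype=float)
            elif nmds_df is not None and var in nmds_df.columns:
                values = nmds_df[var].to_numpy(dtype=float)
            else:
                raise ConfigurationError(f"krige variable {var!r} not found")
            scores, ns_map = normal_scores_transform(values)
            emp = empirical_variogram(xy, scores)
            if config.fit_method == "ml":
                model = fit_variogram(
                    method="ml", site_xy=xy, values=scores,
                    fix_smoothness=0.5, seed=seed,
                )
            else:
                model = fit_variogram(emp, method="wls", fix_smoothness=0.5, seed=seed)
            surface = ordinary_kriging(xy, scores, model, grid, ns_map=ns_map)
            sio.write_surface(surface, out / f"surface_{var}.csv")
            pd.DataFrame(
                {"h": emp.lags, "gamma_hat": emp.gamma, "n_pairs": emp.n_pairs}
            ).to_csv(out / f"variogram_{var}.csv", index=False)
            eff = (
                effective_range(model) if model.partial_sill > 0 else None
            )
            record = model.to_dict() | {"effective_range": eff}
            sio.write_json(record, out / f"model_{var}.json")
            stage["variables"][var] = {
                "nugget": model.nugget,
                "partial_sill": model.partial_sill,
                "range": model.range_,
                "effective_range": eff,
            }
        summary["stages"]["krige"] = stage

    if config.stages.get("validate"):
        seed = child_seed(config.seed, "validate")
        xy = sites[["x", "y"]].to_numpy(dtype=float)
        stage = {"seed": seed, "variables": {}}
        for var in config.krige_variables:
            model_path = out / f"model_{var}.json"
            if not model_path.exists():
                continue
            rec = json.loads(model_path.read_text())
            model = VariogramModel(
                rec["nugget"], rec["partial_sill"], rec["range"], rec["smoothness"]
            )
            nmds_df = (
                pd.read_csv(paths["nmds"]) if Path(paths["nmds"]).exists() else None
            )
            values = (
                sites[var].to_numpy(dtype=float)
                if var in sites.columns
                else nmds_df[var].to_numpy(dtype=float)
            )
            scores, _ = normal_scores_transform(values)
            report = sspe_diagnostics(
                xy, model, scores=scores, n_sim=config.sspe_simulations, seed=seed
            )
            sio.write_json(report.to_dict(), out / f"sspe_{var}.json")
            stage["variables"][var] = report.to_dict()
        summary["stages"]["validate"] = stage

    if config.stages.get("pcnm"):
        xy = sites[["x", "y"]].to_numpy(dtype=float)
        basis = build_pcnm(xy, truncation=config.pcnm_truncation)
        sio.write_pcnm_scores(sites["site_id"], basis.vectors, paths["pcnm"])
        pd.DataFrame({"eigenvalue": basis.eigenvalues}).to_csv(
            out / "pcnm_eigenvalues.csv", index=False
        )
        summary["stages"]["pcnm"] = {
            "truncation": basis.truncation,
            "n_pcnm": basis.vectors.shape[1],
        }

    if config.stages.get("varpart"):
        seed = child_seed(config.seed, "varpart")
        pcnm_df = sio.read_pcnm_scores(paths["pcnm"])
        table = sio.read_community_table(paths["community"]).to_proportions()
        blocks = prepare_blocks(
            sites,
            pcnm_df.drop(columns="site_id"),
            corr_threshold=config.corr_threshold,
        )
        logy = log_relative_abundance(table.data)
        env = pd.concat([blocks.soil, blocks.management], axis=1)
        part_rows, coef_rows = [], []
        for ti, taxon in enumerate(table.taxa):
            y = logy.loc[taxon].to_numpy(dtype=float)
            sel_env = forward_select(
                y, env, alpha=config.alpha, n_perm=config.permutations,
                seed=seed + ti,
            )
            env_cols = sel_env.selected
            resid = y - y.mean()
            if env_cols:
                X = env[env_cols].to_numpy(dtype=float)
                X = X - X.mean(axis=0)
                beta, *_ = np.linalg.lstsq(X, resid, rcond=None)
                resid = resid - X @ beta
            sel_sp = forward_select(
                resid, blocks.space, alpha=config.alpha,
                n_perm=config.permutations, seed=seed + 1000 + ti,
            )
            soil_sel = [c for c in env_cols if c in blocks.soil.columns]
            mgmt_sel = [c for c in env_cols if c in blocks.management.columns]
            res = partition_abundance(
                y, blocks,
                soil_selected=soil_sel,
                management_selected=mgmt_sel,
                space_selected=sel_sp.selected,
                n_perm=config.permutations,
                seed=seed + 2000 + ti,
            )
            part_rows.append(
                {
                    "taxon": taxon,
                    "n_selected": len(env_cols) + len(sel_sp.selected),
                    "soil": res.fractions["soil"],
                    "management": res.fractions["management"],
                    "space": res.fractions["space"],
                    "shared": res.fractions["shared_soil_management"],
                    "residual": res.fractions["residual"],
                    "p_soil": res.p_values.get("soil", np.nan),
                    "p_management": res.p_values.get("management", np.nan),
                    "p_space": res.p_values.get("space", np.nan),
                }
            )
            if env_cols:
                coefs = standardized_coefficients(y, env[env_cols])
                coefs.insert(0, "taxon", taxon)
                coef_rows.append(coefs)
        part_df = pd.DataFrame(part_rows)
        part_df.to_csv(out / "partitions.csv", index=False)
        if coef_rows:
            pd.concat(coef_rows, ignore_index=True).to_csv(
                out / "coefficients.csv", index=False
            )
        stage = {"seed": seed, "n_taxa": len(part_rows),
                 "pruning_log": blocks.pruning_log}
        if Path(paths["distance"]).exists():
            dmat = sio.read_distance_matrix(paths["distance"])
            res = partition_community(
                dmat, blocks, n_perm=config.permutations, seed=seed + 5000
            )
            stage["community"] = {
                "fractions": {k: round(v, 6) for k, v in res.fractions.items()},
                "p_values": {k: round(v, 6) for k, v in res.p_values.items()},
            }
            sio.write_json(stage["community"], out / "community_partition.json")
        summary["stages"]["varpart"] = stage

    sio.write_json(summary, out / "summary.json")
    return summary
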