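"""Config-driven orchestration: simulate-or-load through to model tables.

Stages communicate only via files so every intermediate is inspectable:

    simulate -> clean -> grid -> diversity -> env -> phylo -> sar/ttest -> varpart

Each run writes a manifest (stage list, parameter echo, per-stage row
counts, sha256 of every output) so any number in the model tables can be
regenerated by calling the underlying module function with the manifest's
parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import SMT_POOLED, diversity_table, subset_diversity
from .env_layers import GRADIENT_FLOOR, LGM_YEARS, cell_predictors
from .grids import GridSpec
from .occurrences import assign_cells, build_presence, clean_records, retained
from .phylo import ace_pic, ace_reml, species_niche_values, summarize_signal
from .rasters import read_ascii_grid
from .spatial import all_subsets_average, grid_neighbors, modified_ttest
from .synthetic import WorldConfig, generate_world, write_world
from .varpart import DEFAULT_GROUPS, partition_three

log = logging.getLogger("phylospat")

#: candidate model groups; strongly collinear predictors are separated
MODEL_GROUPS = {
    "a": ["Alt_SD", "MAT", "MAP", "MAT_ano", "MAP_ano", "Vel"],
    "b": ["Alt", "MAT", "MAP", "MAT_ano", "MAP_ano", "Vel"],
    "c": ["Alt_SD", "Alt", "MAT", "MAP", "MAT_ano", "MAP_ano"],
    "d": ["Alt", "MAT", "MAP", "MAT_ano", "MAP_ano", "Vel"],
}


@dataclass
class PipelineConfig:
    outdir: str = "phylospat_run"
    world: WorldConfig = field(default_factory=WorldConfig)
    grid_res: float = 1.0
    niche_res: float = 0.25
    n_perm: int = 999
    min_cells: int = 30                      # refuse regression on fewer cells
    model_groups: dict = field(default_factory=lambda: dict(MODEL_GROUPS))
    varpart_groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    collinearity_threshold: float = 0.7
    velocity_years: int = LGM_YEARS
    velocity_eps: float = GRADIENT_FLOOR
    run_phylo: bool = True
    run_smt: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        blob = yaml.safe_load(Path(path).read_text()) or {}
        world = WorldConfig(**blob.pop("world", {}))
        cfg = cls(world=world, **blob)
        cfg.world.seed = cfg.world.seed or cfg.seed
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic world; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": [], "files": {},
                      "params": json.loads(json.dumps(asdict(config), default=str))}

    def record(stage: str, files: dict[str, Path], **counts):
        manifest["stages"].append({"stage": stage, **counts})
        for name, p in files.items():
            manifest["files"][str(p.relative_to(out))] = _sha256(Path(p))
        log.info("stage %s done (%s)", stage, counts)

    # ---- simulate
    world = generate_world(config.world)
    paths = write_world(world, out / "world")
    record("simulate", paths, n_records=len(world.records),
           n_species=world.config.n_species)

    # ---- clean
    cleaned = clean_records(world.records)
    kept = retained(cleaned)
    p = out / "occurrences_clean.csv"
    cleaned.to_csv(p, index=False)
    record("clean", {"clean": p}, n_in=len(cleaned), n_retained=len(kept))

    # ---- grid + diversity
    grid = GridSpec(config.grid_res)
    P = build_presence(assign_cells(kept, grid), grid)
    div = diversity_table(P, grid)
    p = out / "diversity_all.csv"
    div.to_csv(p, index=False)
    files = {"diversity": p}
    smt_div = None
    if config.run_smt and len(world.truth.smt_table):
        try:
            smt_div = subset_diversity(P, world.truth.smt_table, SMT_POOLED)
            p2 = out / "diversity_smt.csv"
            smt_div.to_csv(p2, index=False)
            files["diversity_smt"] = p2
        except ValueError as exc:
            warnings.warn(f"SMT diversity skipped: {exc}", stacklevel=2)
    record("diversity", files, n_cells=len(div), n_species=P.shape[1])
    _write_cell_geojson(div, grid, out / "cells.geojson")

    # ---- env predictors
    env = cell_predictors(world.altitude, world.climate["mat"], world.climate["map"],
                          world.climate["lgm_mat"], world.climate["lgm_map"], grid,
                          years=config.velocity_years, eps=config.velocity_eps)
    p = out / "cell_predictors.csv"
    env.to_csv(p)
    record("env", {"env": p}, n_cells=len(env))

    # ---- phylo
    if config.run_phylo:
        layers = {"Alt": world.altitude,
                  "MAT": world.climate["mat"], "MAP": world.climate["map"]}
        niche = species_niche_values(kept, layers, GridSpec(config.niche_res))
        signal = summarize_signal(world.tree, niche, n_perm=config.n_perm,
                                  seed=config.seed + 11)
        pic = ace_pic(world.tree, niche["Alt"])
        reml = ace_reml(world.tree, niche["Alt"])
        ace = pd.concat([pic.table(world.tree), reml.table(world.tree)],
                        ignore_index=True)
        f = {"niche": out / "species_niche.csv",
             "signal": out / "phylo_signal.csv",
             "ace": out / "ancestral_altitude.csv"}
        niche.to_csv(f["niche"])
        signal.to_csv(f["signal"], index=False)
        ace.to_csv(f["ace"], index=False)
        record("phylo", f, n_species=len(niche),
               root_pic=round(pic.root_state, 1), root_reml=round(reml.root_state, 1))

    # ---- SAR model averaging
    table = div.merge(env, on="cell_id").dropna()
    if len(table) < config.min_cells:
        raise RuntimeError(f"only {len(table)} usable cells; need {config.min_cells}")
    weights = grid_neighbors(table["cell_id"].to_numpy(), grid)
    table = table.set_index("cell_id").loc[weights.cell_ids]
    model_rows = []

    def run_group(gname: str, resp_table: pd.DataFrame, wts, tag: str):
        for resp in ("SR", "WE"):
            try:
                ms = all_subsets_average(
                    resp_table[resp], resp_table[config.model_groups[gname]], wts,
                    collinearity_threshold=config.collinearity_threshold)
            except ValueError as exc:
                warnings.warn(f"model group {gname} ({tag}, {resp}) skipped: {exc}",
                              stacklevel=2)
                continue
            t = ms.table()
            t.insert(0, "response", resp)
            t.insert(0, "dataset", tag)
            t.insert(0, "model_group", gname)
            t["R2"] = ms.r2
            t["w1"] = ms.w1
            model_rows.append(t)

    for gname in ("a", "b"):
        run_group(gname, table, weights, "all")
    if smt_div is not None and len(smt_div) >= config.min_cells:
        smt_table = smt_div.merge(env, on="cell_id").dropna().set_index("cell_id")
        smt_weights = grid_neighbors(smt_table.index.to_numpy(), grid)
        smt_table = smt_table.loc[smt_weights.cell_ids]
        for gname in ("c", "d"):
            run_group(gname, smt_table, smt_weights, "smt")
    sar = pd.concat(model_rows, ignore_index=True)
    p = out / "sar_models.csv"
    sar.to_csv(p, index=False)
    record("sar", {"sar": p}, n_models=len(model_rows), n_cells=len(table))

    # ---- modified t-test: SMT diversity vs total diversity
    if smt_div is not None and len(smt_div) >= 10:
        joined = div.merge(smt_div[["cell_id", "SR", "WE"]], on="cell_id",
                           suffixes=("", "_smt")).dropna()
        rows = []
        for resp in ("SR", "WE"):
            res = modified_ttest(joined[f"{resp}_smt"], joined[resp],
                                 joined["lon_center"], joined["lat_center"])
            rows.append({"pair": f"{resp}_smt~{resp}", "rho": res.r,
                         "m_hat": res.m_hat, "t": res.t, "p": res.p, "n": res.n})
        tt = pd.DataFrame(rows)
        p = out / "modified_ttest.csv"
        tt.to_csv(p, index=False)
        record("ttest", {"ttest": p}, n_pairs=len(tt))

    # ---- variance partitioning
    vp_rows = []
    gnames = tuple(config.varpart_groups)
    for resp in ("SR", "WE"):
        vp = partition_three(
            table[resp],
            *(table[cols] for cols in config.varpart_groups.values()),
            group_names=gnames)
        t = vp.table()
        t.insert(0, "response", resp)
        vp_rows.append(t)
    vp = pd.concat(vp_rows, ignore_index=True)
    p = out / "varpart.csv"
    vp.to_csv(p, index=False)
    record("varpart", {"varpart": p}, n_fractions=len(vp))

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_cell_geojson(div: pd.DataFrame, grid: GridSpec, path: Path) -> None:
    feats = []
    for _, row in div.iterrows():
        ring = grid.cell_polygon(int(row["cell_id"]))
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [[list(c) for c in ring]]},
            "properties": {"cell_id": int(row["cell_id"]),
                           "SR": int(row["SR"]), "WE": float(row["WE"])},
        })
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def load_layers(paths: dict[str, str]) -> dict:
    """Read a named set of ASCII-grid layers from disk."""
    out: dict = {}
    for name, p in paths.items():
        if isinstance(p, (list, tuple)):
            out[name] = [read_ascii_grid(q) for q in p]
        else:
            out[name] = read_ascii_grid(p)
    return out
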