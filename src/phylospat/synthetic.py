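"""Synthetic world generator with known ground truth.

Emulates the data regime of a northern-hemisphere alpine radiation: a
landscape with a high-relief plateau embedded in smooth lowlands,
lapse-rate-coupled climate, Last Glacial Maximum (LGM) climate layers whose
anomaly grows with latitude, a Yule phylogeny whose tips carry
Brownian-motion altitude niche optima, and occurrence records placed by
Gaussian niche matching down-weighted where the glacial-interglacial
anomaly and climate-change velocity are high. Richness and endemism built
this way increase with altitude and topographic heterogeneity and decrease
with climate instability — the qualitative regime the downstream pipeline
must recover.

Determinism: one global seed; each stage draws from a child generator at a
fixed offset (terrain +1, climate +2, tree +3, traits +4, occurrences +5,
corruption +6), so stages are independently reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .env_layers import climate_anomaly, climate_velocity, spatial_gradient
from .grids import GridSpec
from .rasters import RasterLayer, write_ascii_grid
from .diversity import SMT_GROUPS

__all__ = ["WorldConfig", "SyntheticTruth", "World", "make_terrain",
           "make_climate", "simulate_tree", "simulate_bm_traits",
           "simulate_occurrences", "generate_world", "write_world"]


@dataclass
class WorldConfig:
    """Generator settings; the defaults define the package's study conditions."""

    # extent and resolution
    extent: tuple[float, float, float, float] = (60.0, 120.0, 5.0, 65.0)  # W,E,S,N
    res: float = 0.25                       # raster resolution, degrees

    # terrain
    flat: bool = False                      # degenerate flat-world mode
    base_altitude: float = 400.0            # m, lowland baseline
    lowland_relief_sd: float = 60.0         # m, within-cell relief of lowlands
    plateau_relief_factor: float = 8.0      # plateau relief = factor x lowland
    plateau_height: float = 3600.0          # m, added inside the plateau
    plateau_box: tuple[float, float, float, float] = (75.0, 105.0, 22.0, 48.0)

    # modern climate
    lapse_rate: float = -0.006              # degC per m (negative)
    t_sea_level: float = 35.0               # degC at latitude 0, sea level
    t_lat_gain: float = 0.8                 # degC cooling per degree |latitude|
    t_noise_sd: float = 8.0                 # degC, smooth continentality noise
    map_base: float = 600.0                 # mm at the western margin
    map_lon_gain: float = 20.0              # mm per degree eastward (monsoon)
    map_oro_gain: float = 0.08              # mm per m altitude (orographic)

    # LGM climate
    lgm_cooling_base: float = 4.0           # degC
    lgm_latitude_gain: float = 0.05         # degC per degree |latitude|
    lgm_pattern_sd: float = 2.5             # degC, latitude-independent anomaly pattern
    lgm_map_base: float = 150.0             # mm drier at the LGM
    lgm_map_latitude_gain: float = 2.0      # mm per degree |latitude|
    lgm_map_pattern_sd: float = 80.0        # mm, anomaly pattern
    model_noise_sd: float = 0.5             # degC, per-paleomodel smooth noise
    model_noise_sd_map: float = 40.0        # mm

    # phylogeny and niches
    n_species: int = 60
    n_tips: int = 60
    tree_depth: float = 17.0                # root age, arbitrary time units
    bm_root: float = 3800.0                 # m, ancestral altitude optimum
    bm_sigma2: float = 1.5e5                # m^2 per unit branch length

    # occurrence sampling
    records_per_species: int = 120
    niche_breadth: float = 350.0            # m, Gaussian niche SD
    anomaly_penalty_quantile: float = 0.5   # logistic midpoint (layer quantile)
    velocity_penalty_quantile: float = 0.35
    penalty_softness: float = 0.2           # anomaly logistic scale, x layer SD
    velocity_penalty_softness: float = 0.1  # velocity logistic scale, x layer SD
    corrupt_fraction: float = 0.05
    smt_fraction: float = 0.3               # share of species carrying an SMT

    seed: int = 0

    def __post_init__(self) -> None:
        w, e, s, n = self.extent
        if not (w < e and s < n):
            raise ValueError("extent is empty")
        if not (-180 <= w and e <= 180 and -90 <= s and n <= 90):
            raise ValueError("extent outside the world")
        if self.res <= 0:
            raise ValueError("res must be positive")
        if (e - w) < self.res or (n - s) < self.res:
            raise ValueError("extent smaller than one raster cell")
        if self.n_tips != self.n_species:
            raise ValueError("n_tips must equal n_species")
        if self.bm_sigma2 < 0:
            raise ValueError("bm_sigma2 must be non-negative")

    def rng(self, stage_offset: int) -> np.random.Generator:
        return np.random.default_rng(self.seed + stage_offset)


@dataclass
class SyntheticTruth:
    """Everything needed to score what the pipeline recovers."""

    niche_optima: dict[str, float]
    coefficients: dict[str, float]          # realized generator coefficients
    cell_drivers: pd.DataFrame              # per-1deg-cell alt, alt_sd, anomaly, velocity
    corrupt_rows: list[int]                 # row positions of appended bad records
    corrupt_kinds: list[str]
    smt_table: pd.DataFrame                 # long (species, group) membership

    def to_json(self, path: str | Path) -> None:
        blob = {
            "niche_optima": self.niche_optima,
            "coefficients": self.coefficients,
            "cell_drivers": self.cell_drivers.reset_index().to_dict(orient="list"),
            "corrupt_rows": self.corrupt_rows,
            "corrupt_kinds": self.corrupt_kinds,
            "smt_table": self.smt_table.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(blob, indent=1))


def _smooth_field(shape, sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma_px, mode="reflect")
    return f / f.std()


def _raster_shape(config: WorldConfig):
    w, e, s, n = config.extent
    return round((n - s) / config.res), round((e - w) / config.res)


def make_terrain(config: WorldConfig) -> RasterLayer:
    """Altitude raster: smooth lowlands plus a rough high plateau, metres."""
    nrow, ncol = _raster_shape(config)
    w, _, s, _ = config.extent
    if config.flat:
        return RasterLayer(np.full((nrow, ncol), config.base_altitude),
                           w, s, config.res, units="m")
    rng = config.rng(1)
    broad = _smooth_field((nrow, ncol), 8.0, rng) * 150.0
    micro = _smooth_field((nrow, ncol), 1.2, rng) * config.lowland_relief_sd
    layer = RasterLayer(np.zeros((nrow, ncol)), w, s, config.res, units="m")
    lon, lat = layer.pixel_centers()
    pw, pe, ps, pn = config.plateau_box
    edge = 1.0  # degrees over which the plateau shoulder rises
    mask = (1 / (1 + np.exp(-(lon - pw) / edge)) * 1 / (1 + np.exp((lon - pe) / edge))
            * 1 / (1 + np.exp(-(lat - ps) / edge)) * 1 / (1 + np.exp((lat - pn) / edge)))
    rough = _smooth_field((nrow, ncol), 1.2, rng)
    relief = config.lowland_relief_sd * config.plateau_relief_factor
    alt = (config.base_altitude + broad + micro
           + mask * (config.plateau_height + rough * relief))
    layer.values = np.maximum(alt, 0.0)
    return layer


def make_climate(altitude: RasterLayer, config: WorldConfig) -> dict:
    """Modern MAT/MAP plus two perturbed LGM model layers for each.

    MAT follows a sea-level latitudinal gradient plus a lapse-rate term; MAP
    follows an eastward monsoon gradient plus an orographic term. Each LGM
    model layer is the modern layer minus a latitude-growing cooling (or
    drying), perturbed by its own smooth noise field.
    """
    rng = config.rng(2)
    lon, lat = altitude.pixel_centers()
    alt = altitude.values
    mat = (config.t_sea_level - config.t_lat_gain * np.abs(lat)
           + config.lapse_rate * alt)
    if config.t_noise_sd > 0:
        mat = mat + _smooth_field(alt.shape, 10.0, rng) * config.t_noise_sd
    map_mod = np.maximum(
        config.map_base + config.map_lon_gain * (lon - config.extent[0])
        + config.map_oro_gain * alt, 0.0)
    shape = alt.shape
    cooling = config.lgm_cooling_base + config.lgm_latitude_gain * np.abs(lat)
    if config.lgm_pattern_sd > 0:
        cooling = cooling + _smooth_field(shape, 8.0, rng) * config.lgm_pattern_sd
    drying = config.lgm_map_base + config.lgm_map_latitude_gain * np.abs(lat)
    if config.lgm_map_pattern_sd > 0:
        drying = drying + _smooth_field(shape, 8.0, rng) * config.lgm_map_pattern_sd
    lgm_mat, lgm_map = [], []
    for _ in range(2):
        noise_t = (_smooth_field(shape, 6.0, rng) * config.model_noise_sd
                   if config.model_noise_sd > 0 else 0.0)
        noise_p = (_smooth_field(shape, 6.0, rng) * config.model_noise_sd_map
                   if config.model_noise_sd_map > 0 else 0.0)
        lgm_mat.append(altitude.copy_with(mat - cooling + noise_t, units="degC"))
        lgm_map.append(altitude.copy_with(np.maximum(map_mod - drying + noise_p, 0.0),
                                          units="mm"))
    return {
        "mat": altitude.copy_with(mat, units="degC"),
        "map": altitude.copy_with(map_mod, units="mm"),
        "lgm_mat": lgm_mat,
        "lgm_map": lgm_map,
    }


def simulate_tree(n_tips: int, seed: int, depth: float = 1.0) -> dendropy.Tree:
    """Yule (pure-birth) tree, ultrametric, scaled to the given root depth.

    Tips are labelled sp0001, sp0002, ... in left-to-right order.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    # active lineages as mutable [children, branch_length] records
    root = [None, 0.0]
    a, b = [None, 0.0], [None, 0.0]
    root[0] = [a, b]
    active = [a, b]
    while len(active) < n_tips:
        dt = rng.exponential(1.0 / len(active))
        for node in active:
            node[1] += dt
        i = rng.integers(len(active))
        node = active.pop(i)
        c1, c2 = [None, 0.0], [None, 0.0]
        node[0] = [c1, c2]
        active.extend([c1, c2])
    dt = rng.exponential(1.0 / n_tips)
    for node in active:
        node[1] += dt

    height = 0.0
    probe = root
    while probe[0] is not None:
        probe = probe[0][0]
        height += probe[1]
    scale = depth / height
    counter = [0]

    def newick(node) -> str:
        if node[0] is None:
            counter[0] += 1
            return f"sp{counter[0]:04d}:{node[1] * scale:.10f}"
        kids = ",".join(newick(c) for c in node[0])
        return f"({kids}):{node[1] * scale:.10f}"

    text = f"({newick(root[0][0])},{newick(root[0][1])});"
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    return tree


def simulate_bm_traits(tree: dendropy.Tree, root_value: float, sigma2: float,
                       seed: int) -> pd.Series:
    """Brownian-motion tip values: child = parent + N(0, sigma2 * branch)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    value = {tree.seed_node: root_value}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        step = rng.normal(0.0, np.sqrt(sigma2 * node.edge.length))
        value[node] = value[node.parent_node] + step
    tips = {lf.taxon.label: value[lf] for lf in tree.leaf_node_iter()}
    return pd.Series(tips, name="niche_optimum")


def _logistic_down(v: np.ndarray, mid: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip((v - mid) / scale, -40, 40)))


def simulate_occurrences(tree: dendropy.Tree, traits: pd.Series, layers: dict,
                         config: WorldConfig):
    """Niche-matched occurrence records plus ground truth.

    Per species, pixels are sampled with probability proportional to a
    Gaussian match between the species' altitude optimum and pixel altitude,
    multiplied by logistic down-weights in the pixel's LGM temperature
    anomaly and climate-change velocity. A configurable fraction of corrupt
    records (zero coordinates, lat == lon, out of range) is appended, never
    overwriting clean rows, and indexed in the truth object.
    """
    alt_layer = layers["altitude"]
    ano = climate_anomaly(layers["mat"], layers["lgm_mat"])
    vel = climate_velocity(ano, spatial_gradient(layers["mat"]))
    for lay in (ano, vel):
        if not alt_layer.same_geometry(lay):
            raise ValueError("layers do not share extent/resolution")

    a = ano.values[ano.mask]
    v = vel.values[vel.mask]
    ano_mid = float(np.quantile(a, config.anomaly_penalty_quantile))
    ano_scale = float(config.penalty_softness * a.std())
    vel_mid = float(np.quantile(v, config.velocity_penalty_quantile))
    vel_scale = float(config.velocity_penalty_softness * v.std())

    lon, lat = alt_layer.pixel_centers()
    penalty = (_logistic_down(ano.values, ano_mid, ano_scale)
               * _logistic_down(vel.values, vel_mid, vel_scale))

    rng = config.rng(5)
    rows = []
    nb2 = 2.0 * config.niche_breadth ** 2
    flat_lon, flat_lat = lon.ravel(), lat.ravel()
    flat_alt, flat_pen = alt_layer.values.ravel(), penalty.ravel()
    for sp in traits.index:
        w = np.exp(-((flat_alt - traits[sp]) ** 2) / nb2) * flat_pen
        total = w.sum()
        if total <= 1e-12:
            warnings.warn(f"species {sp} has no habitable area; 0 records",
                          stacklevel=2)
            continue
        idx = rng.choice(len(w), size=config.records_per_species, p=w / total)
        jit_lon = rng.uniform(-config.res / 2, config.res / 2, len(idx))
        jit_lat = rng.uniform(-config.res / 2, config.res / 2, len(idx))
        for i, jx, jy in zip(idx, jit_lon, jit_lat):
            rows.append((sp, flat_lon[i] + jx, flat_lat[i] + jy))
    records = pd.DataFrame(rows, columns=["species", "lon", "lat"])

    crng = config.rng(6)
    n_clean = len(records)
    n_corrupt = round(config.corrupt_fraction * n_clean)
    kinds, bad_rows = [], []
    kinds_cycle = ("zero", "equal", "invalid")
    for i in range(n_corrupt):
        kind = kinds_cycle[i % 3]
        sp = traits.index[crng.integers(len(traits))]
        if kind == "zero":
            row = (sp, 0.0, 0.0)
        elif kind == "equal":
            c = float(crng.uniform(5, 60))
            row = (sp, c, c)
        else:
            row = (sp, float(crng.uniform(181, 300)), float(crng.uniform(-89, 89)))
        bad_rows.append(n_clean + i)
        kinds.append(kind)
        records.loc[n_clean + i] = row

    # per-1-degree-cell driver fields, straight from the generator's layers
    grid = GridSpec(1.0)
    cell = grid.cell_id(lon[alt_layer.mask], lat[alt_layer.mask])
    drivers = pd.DataFrame({
        "alt": alt_layer.values[alt_layer.mask],
        "anomaly": ano.values[alt_layer.mask],
        "velocity": vel.values[alt_layer.mask],
    }, index=cell)
    g = drivers.groupby(level=0)
    cell_drivers = g.mean()
    cell_drivers["alt_sd"] = drivers["alt"].groupby(level=0).std(ddof=1)
    cell_drivers.index.name = "cell_id"

    # SMT membership: altitude-biased — high-optimum species carry syndromes
    srng = config.rng(7)
    n_smt = round(config.smt_fraction * len(traits))
    ranked = traits.sort_values(ascending=False).index[: max(2 * n_smt, n_smt)]
    members = srng.choice(len(ranked), size=n_smt, replace=False)
    smt = pd.DataFrame({
        "species": [ranked[i] for i in sorted(members)],
        "group": [SMT_GROUPS[srng.integers(len(SMT_GROUPS))] for _ in range(n_smt)],
    })

    truth = SyntheticTruth(
        niche_optima={k: float(t) for k, t in traits.items()},
        coefficients={
            "niche_breadth": config.niche_breadth,
            "anomaly_midpoint": ano_mid, "anomaly_scale": ano_scale,
            "velocity_midpoint": vel_mid, "velocity_scale": vel_scale,
            "records_per_species": config.records_per_species,
            "corrupt_fraction": config.corrupt_fraction,
        },
        cell_drivers=cell_drivers,
        corrupt_rows=bad_rows,
        corrupt_kinds=kinds,
        smt_table=smt,
    )
    return records, truth


@dataclass
class World:
    config: WorldConfig
    altitude: RasterLayer
    climate: dict
    tree: dendropy.Tree
    traits: pd.Series
    records: pd.DataFrame
    truth: SyntheticTruth

    @property
    def layers(self) -> dict:
        return {"altitude": self.altitude, **self.climate}


def generate_world(config: WorldConfig | None = None) -> World:
    """Run every stage of the generator under the config's seed."""
    config = config or WorldConfig()
    altitude = make_terrain(config)
    climate = make_climate(altitude, config)
    tree = simulate_tree(config.n_tips, seed=config.seed + 3,
                         depth=config.tree_depth)
    traits = simulate_bm_traits(tree, config.bm_root, config.bm_sigma2,
                                seed=config.seed + 4)
    records, truth = simulate_occurrences(
        tree, traits, {"altitude": altitude, **climate}, config)
    return World(config, altitude, climate, tree, traits, records, truth)


def write_world(world: World, outdir: str | Path) -> dict[str, Path]:
    """Serialize the bundle: CSV records, ASCII grids, newick tree, JSON truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    occ = world.records.rename(columns={"lon": "decimalLongitude",
                                        "lat": "decimalLatitude"})
    paths["occurrences"] = outdir / "occurrences.csv"
    occ.to_csv(paths["occurrences"], index=False)
    grids = {"altitude": world.altitude, "mat": world.climate["mat"],
             "map": world.climate["map"]}
    for i, lay in enumerate(world.climate["lgm_mat"], 1):
        grids[f"lgm_mat_model{i}"] = lay
    for i, lay in enumerate(world.climate["lgm_map"], 1):
        grids[f"lgm_map_model{i}"] = lay
    for name, lay in grids.items():
        paths[name] = outdir / f"{name}.asc"
        write_ascii_grid(lay, paths[name])
    paths["tree"] = outdir / "tree.nwk"
    world.tree.write(path=str(paths["tree"]), schema="newick",
                     suppress_rooting=True, unquoted_underscores=True)
    paths["traits"] = outdir / "niche_optima.csv"
    world.traits.rename_axis("species").to_csv(paths["traits"])
    paths["smt"] = outdir / "smt_groups.csv"
    world.truth.smt_table.to_csv(paths["smt"], index=False)
    paths["truth"] = outdir / "truth.json"
    world.truth.to_json(paths["truth"])
    paths["config"] = outdir / "world_config.json"
    paths["config"].write_text(json.dumps(asdict(world.config), indent=1))
    return paths
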