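"""The seven per-cell environmental predictors.

Alt      mean altitude in a cell (m) — proxy for alpine exposure
Alt_SD   standard deviation of altitude in a cell (m) — topographic
         heterogeneity / orogenic uplift
MAT      modern mean annual temperature (degC)
MAP      modern mean annual precipitation (mm)
MAT_ano  modern MAT minus LGM MAT (degC), LGM = mean of the paleoclimate
         model ensemble; sign convention modern-minus-LGM throughout
MAP_ano  likewise for precipitation (mm)
Vel      glacial-interglacial climate-change velocity (m/yr): temporal MAT
         change rate divided by the local spatial MAT gradient — the speed
         a temperature isoline has moved since the LGM

Cell aggregation takes the statistic over all valid pixels whose centers
fall in the cell; anomaly and velocity are computed per pixel and then
averaged per cell.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .grids import M_PER_DEG, GridSpec
from .rasters import RasterLayer, require_aligned

LGM_YEARS = 21_000
GRADIENT_FLOOR = 1e-9  # degC/m; guards the velocity division on flat terrain

PREDICTORS = ("Alt", "Alt_SD", "MAT", "MAP", "MAT_ano", "MAP_ano", "Vel")


def cell_summary(layer: RasterLayer, grid: GridSpec, stat: str = "mean",
                 ddof: int = 1) -> pd.Series:
    """Aggregate a raster to per-cell values (``stat`` in {'mean', 'sd'}).

    SD defaults to the sample (n-1) estimator; ``ddof=0`` gives the
    population form. Cells with zero valid pixels are simply absent from the
    returned Series (index = cell_id).
    """
    if stat not in ("mean", "sd"):
        raise ValueError(f"stat must be 'mean' or 'sd', got {stat!r}")
    if layer.res > grid.res + 1e-12:
        raise ValueError("raster must be at least as fine as the target grid")
    lon, lat = layer.pixel_centers()
    ok = layer.mask
    cells = grid.cell_id(lon[ok], lat[ok])
    vals = pd.Series(layer.values[ok], index=cells)
    g = vals.groupby(level=0)
    out = g.mean() if stat == "mean" else g.std(ddof=ddof).fillna(0.0)
    out.index.name = "cell_id"
    return out


def climate_anomaly(modern: RasterLayer, lgm_models: Sequence[RasterLayer]) -> RasterLayer:
    """Pixelwise modern minus the mean of the LGM model ensemble."""
    if len(lgm_models) == 0:
        raise ValueError("need at least one LGM model layer")
    require_aligned(modern, *lgm_models)
    lgm_mean = np.mean([m.values for m in lgm_models], axis=0)
    ano = modern.values - lgm_mean
    bad = ~modern.mask | ~np.logical_and.reduce([m.mask for m in lgm_models])
    ano[bad] = modern.nodata
    return modern.copy_with(ano)


def spatial_gradient(layer: RasterLayer) -> RasterLayer:
    """Magnitude of the local spatial gradient, in layer-units per metre.

    Central differences in the interior, one-sided at edges; the east-west
    pixel spacing shrinks with cos(latitude).
    """
    if layer.nrow < 3 or layer.ncol < 3:
        raise ValueError("gradient needs at least a 3x3 raster")
    vals = np.where(layer.mask, layer.values, np.nan)
    dy_m = layer.res * M_PER_DEG
    _, lat = layer.pixel_centers()
    dx_m = dy_m * np.cos(np.radians(lat))
    # rows run north->south, so the row axis points in -latitude; magnitude
    # is unaffected by the sign
    d_row, d_col = np.gradient(vals)
    slope = np.hypot(d_col / dx_m, d_row / dy_m)
    slope[~np.isfinite(slope)] = layer.nodata
    return layer.copy_with(slope, units=f"{layer.units}/m")


def climate_velocity(anomaly: RasterLayer, gradient: RasterLayer,
                     years: int = LGM_YEARS, eps: float = GRADIENT_FLOOR) -> RasterLayer:
    """Vel = (|anomaly| / years) / max(gradient, eps), metres per year."""
    if years <= 0:
        raise ValueError("years must be positive")
    require_aligned(anomaly, gradient)
    ok = anomaly.mask & gradient.mask
    vel = np.full_like(anomaly.values, anomaly.nodata)
    vel[ok] = (np.abs(anomaly.values[ok]) / years) / np.maximum(gradient.values[ok], eps)
    return anomaly.copy_with(vel, units="m/yr")


def cell_predictors(
    altitude: RasterLayer,
    mat: RasterLayer,
    map_: RasterLayer,
    lgm_mat: Sequence[RasterLayer],
    lgm_map: Sequence[RasterLayer],
    grid: GridSpec,
    years: int = LGM_YEARS,
    eps: float = GRADIENT_FLOOR,
    sd_ddof: int = 1,
) -> pd.DataFrame:
    """Assemble the full seven-predictor table, indexed by cell_id."""
    require_aligned(altitude, mat, map_, *lgm_mat, *lgm_map)
    mat_ano = climate_anomaly(mat, lgm_mat)
    map_ano = climate_anomaly(map_, lgm_map)
    vel = climate_velocity(mat_ano, spatial_gradient(mat), years=years, eps=eps)
    cols = {
        "Alt": cell_summary(altitude, grid, "mean"),
        "Alt_SD": cell_summary(altitude, grid, "sd", ddof=sd_ddof),
        "MAT": cell_summary(mat, grid, "mean"),
        "MAP": cell_summary(map_, grid, "mean"),
        "MAT_ano": cell_summary(mat_ano, grid, "mean"),
        "MAP_ano": cell_summary(map_ano, grid, "mean"),
        "Vel": cell_summary(vel, grid, "mean"),
    }
    out = pd.DataFrame(cols)
    out.index.name = "cell_id"
    return out
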