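"""Regular lon/lat raster layers with ESRI ASCII grid text I/O.

A :class:`RasterLayer` stores a 2-D value array in map orientation (row 0 is
the northernmost row), an origin at the lower-left corner, a square cell size
in degrees, a nodata marker and a unit string. All layers that are analysed
together must share the same geotransform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA_DEFAULT = -9999.0


@dataclass
class RasterLayer:
    values: np.ndarray              # (nrow, ncol), row 0 = north
    xll: float                      # lower-left corner longitude
    yll: float                      # lower-left corner latitude
    res: float                      # cell size, degrees
    nodata: float = NODATA_DEFAULT
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.res <= 0:
            raise ValueError("raster resolution must be positive")

    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """True where a pixel holds a valid value."""
        return (self.values != self.nodata) & np.isfinite(self.values)

    def pixel_centers(self):
        """(lon, lat) arrays of shape (nrow, ncol) at pixel centers."""
        lon = self.xll + (np.arange(self.ncol) + 0.5) * self.res
        lat_top_down = self.yll + (self.nrow - np.arange(self.nrow) - 0.5) * self.res
        return np.meshgrid(lon, lat_top_down)

    def same_geometry(self, other: "RasterLayer") -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.xll - other.xll) < 1e-9
            and abs(self.yll - other.yll) < 1e-9
            and abs(self.res - other.res) < 1e-9
        )

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "RasterLayer":
        return RasterLayer(np.array(values, dtype=float), self.xll, self.yll,
                           self.res, self.nodata, self.units if units is None else units)


def require_aligned(*layers: RasterLayer) -> None:
    ref = layers[0]
    for lay in layers[1:]:
        if not ref.same_geometry(lay):
            raise ValueError(
                "raster layers are not aligned: "
                f"{(ref.nrow, ref.ncol, ref.xll, ref.yll, ref.res)} vs "
                f"{(lay.nrow, lay.ncol, lay.xll, lay.yll, lay.res)}"
            )


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    """Write one layer as an ESRI ASCII grid (plain text)."""
    path = Path(path)
    header = (
        f"ncols {layer.ncol}\n"
        f"nrows {layer.nrow}\n"
        f"xllcorner {layer.xll!r}\n"
        f"yllcorner {layer.yll!r}\n"
        f"cellsize {layer.res!r}\n"
        f"NODATA_value {layer.nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, layer.values, fmt="%.8g")


def read_ascii_grid(path: str | Path, units: str = "") -> RasterLayer:
    path = Path(path)
    meta: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    if values.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(f"ASCII grid {path} body does not match its header")
    return RasterLayer(values, meta["xllcorner"], meta["yllcorner"],
                       meta["cellsize"], meta.get("nodata_value", NODATA_DEFAULT),
                       units)
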