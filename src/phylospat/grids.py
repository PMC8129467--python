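"""Global lon/lat grid conventions and great-circle geometry.

Cells live on a regular grid anchored at (-180, -90). A record at (lon, lat)
falls in the half-open cell [edge, edge + res) in both axes; the upper world
boundary (lon = 180, lat = 90) is clamped into the last column/row so that
every valid coordinate maps to exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_008.8
#: metres per degree of latitude (and of longitude at the equator)
M_PER_DEG = EARTH_RADIUS_M * np.pi / 180.0

GRID_ORIGIN = (-180.0, -90.0)


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid anchored at (-180, -90).

    ``res`` must divide both 360 and 180 into whole cells (1, 0.5 and 0.25
    degrees all qualify).
    """

    res: float = 1.0

    def __post_init__(self) -> None:
        if self.res <= 0:
            raise ValueError(f"grid resolution must be positive, got {self.res}")
        for span in (360.0, 180.0):
            n = span / self.res
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"resolution {self.res} does not evenly divide {span} degrees"
                )

    @property
    def ncol(self) -> int:
        return round(360.0 / self.res)

    @property
    def nrow(self) -> int:
        return round(180.0 / self.res)

    def colrow(self, lon, lat):
        """Map coordinates to (col, row); half-open cells, top edge clamped."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - GRID_ORIGIN[0]) / self.res).astype(np.int64)
        row = np.floor((lat - GRID_ORIGIN[1]) / self.res).astype(np.int64)
        col = np.clip(col, 0, self.ncol - 1)
        row = np.clip(row, 0, self.nrow - 1)
        return col, row

    def cell_id(self, lon, lat):
        """Scalar cell id, bijective with (col, row): id = row * ncol + col."""
        col, row = self.colrow(lon, lat)
        return row * self.ncol + col

    def id_to_colrow(self, cell_id):
        cell_id = np.asarray(cell_id, dtype=np.int64)
        return cell_id % self.ncol, cell_id // self.ncol

    def cell_center(self, cell_id):
        """(lon, lat) of cell centroids."""
        col, row = self.id_to_colrow(cell_id)
        lon = GRID_ORIGIN[0] + (col + 0.5) * self.res
        lat = GRID_ORIGIN[1] + (row + 0.5) * self.res
        return lon, lat

    def cell_polygon(self, cell_id):
        """Corner ring [(lon, lat) x 5] of one cell, closed, counter-clockwise."""
        col, row = self.id_to_colrow(np.int64(cell_id))
        x0 = GRID_ORIGIN[0] + float(col) * self.res
        y0 = GRID_ORIGIN[1] + float(row) * self.res
        x1, y1 = x0 + self.res, y0 + self.res
        return [(x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0)]


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between degree coordinates (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_haversine_m(lon, lat):
    """Dense n x n great-circle distance matrix in metres."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return haversine_m(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
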