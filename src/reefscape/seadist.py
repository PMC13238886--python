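"""Least-cost in-water distances over a gridded land/sea mask.

Sea cells become graph nodes; edges join neighboring sea cells and are
weighted by the great-circle (haversine) length between cell centers, so a
Dijkstra shortest path is the shortest route that stays in water.  The
default 16-cell neighborhood (rook + bishop + knight moves) keeps the
lattice-metric overshoot against the true great circle below ~2.4% in the
worst direction; the 8-cell neighborhood is available but coarser (~8%).

Depth is ignored: bathymetry only delineates land (cells with elevation at
or above a threshold, 0 m by default, are land).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .pairwise import PairwiseMatrix

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

DISTANCE_METRIC = "distance_km"

# (row, col) offsets; 16-neighborhood adds knight moves to reduce anisotropy
_OFFSETS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_OFFSETS_16 = _OFFSETS_8 + [
    (-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1),
]


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in km (Earth radius 6371 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


@dataclass
class SeascapeGrid:
    """Regular lon/lat grid with a binary sea mask (True = traversable)."""

    lons: np.ndarray   # cell-center longitudes, length ncols
    lats: np.ndarray   # cell-center latitudes, length nrows
    sea: np.ndarray    # (nrows, ncols) bool

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, float)
        self.lats = np.asarray(self.lats, float)
        self.sea = np.asarray(self.sea, bool)
        if self.sea.shape != (len(self.lats), len(self.lons)):
            raise ValueError("mask shape does not match lon/lat axes")
        for ax in (self.lons, self.lats):
            if len(ax) > 1 and not np.allclose(np.diff(ax), ax[1] - ax[0]):
                raise ValueError("grid spacing must be regular")
        if not self.sea.any():
            raise ValueError("grid has no sea cells")

    @property
    def resolution(self) -> float:
        return float(abs(self.lons[1] - self.lons[0])) if len(self.lons) > 1 else np.nan

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return float(self.lons[col]), float(self.lats[row])


def read_ascii_grid(path, land_threshold: float = 0.0) -> SeascapeGrid:
    """Read an ESRI ASCII elevation grid; cells with elevation >=
    ``land_threshold`` are land.  NODATA cells are treated as land."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII grid missing header field {key!r}")
    data = np.loadtxt(lines[n_header:]).reshape(
        int(header["nrows"]), int(header["ncols"])
    )
    nodata = header.get("nodata_value")
    cs = header["cellsize"]
    lons = header["xllcorner"] + cs * (np.arange(int(header["ncols"])) + 0.5)
    # ESRI ASCII rows run north to south
    lats = header["yllcorner"] + cs * (np.arange(int(header["nrows"]))[::-1] + 0.5)
    sea = data < land_threshold
    if nodata is not None:
        sea &= data != nodata
    return SeascapeGrid(lons=lons, lats=lats, sea=sea)


def write_ascii_grid(grid: SeascapeGrid, path,
                     sea_value: float = -10.0, land_value: float = 10.0) -> None:
    cs = grid.resolution
    with open(path, "w") as fh:
        fh.write(f"ncols {len(grid.lons)}\n")
        fh.write(f"nrows {len(grid.lats)}\n")
        fh.write(f"xllcorner {grid.lons[0] - cs / 2}\n")
        fh.write(f"yllcorner {grid.lats.min() - cs / 2}\n")
        fh.write(f"cellsize {cs}\n")
        fh.write("NODATA_value -9999\n")
        vals = np.where(grid.sea, sea_value, land_value)
        np.savetxt(fh, vals, fmt="%.1f")


def _passage_blocked(sea: np.ndarray, r: int, c: int, dr: int, dc: int) -> bool:
    """A diagonal or knight move is blocked when the two cells flanking the
    move's path are both land (the channel is pinched shut)."""
    if abs(dr) == 1 and abs(dc) == 1:
        flank = [(r + dr, c), (r, c + dc)]
    elif abs(dr) == 1 and abs(dc) == 2:
        step = dc // 2
        flank = [(r, c + step), (r + dr, c + step)]
    elif abs(dr) == 2 and abs(dc) == 1:
        step = dr // 2
        flank = [(r + step, c), (r + step, c + dc)]
    else:
        return False
    return all(not sea[fr, fc] for fr, fc in flank)


def build_sea_graph(grid: SeascapeGrid, neighborhood: int = 16) -> nx.Graph:
    """Graph of sea cells; edge weights are haversine km between centers."""
    if neighborhood == 8:
        offsets = _OFFSETS_8
    elif neighborhood == 16:
        offsets = _OFFSETS_16
    else:
        raise ValueError("neighborhood must be 8 or 16")
    nrows, ncols = grid.sea.shape
    g = nx.Graph()
    sea_cells = np.argwhere(grid.sea)
    g.add_nodes_from(map(tuple, sea_cells))
    for r, c in sea_cells:
        lon1, lat1 = grid.cell_center(r, c)
        for dr, dc in offsets:
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < nrows and 0 <= c2 < ncols):
                continue
            if not grid.sea[r2, c2]:
                continue
            if (r2, c2) <= (r, c):  # add each undirected edge once
                continue
            if _passage_blocked(grid.sea, r, c, dr, dc):
                continue
            lon2, lat2 = grid.cell_center(r2, c2)
            g.add_edge((r, c), (r2, c2),
                       weight=float(haversine_km(lon1, lat1, lon2, lat2)))
    return g


def snap_to_sea(grid: SeascapeGrid, lon: float, lat: float,
                snap_radius: int = 2) -> tuple[int, int]:
    """Nearest sea cell to a coordinate, searched within ``snap_radius``
    cells of the enclosing cell."""
    col = int(np.argmin(np.abs(grid.lons - lon)))
    row = int(np.argmin(np.abs(grid.lats - lat)))
    best, best_d = None, np.inf
    nrows, ncols = grid.sea.shape
    for r in range(max(0, row - snap_radius), min(nrows, row + snap_radius + 1)):
        for c in range(max(0, col - snap_radius), min(ncols, col + snap_radius + 1)):
            if not grid.sea[r, c]:
                continue
            d = haversine_km(lon, lat, *grid.cell_center(r, c))
            if d < best_d:
                best, best_d = (r, c), d
    if best is None:
        raise ValueError(
            f"no sea cell within {snap_radius} cells of ({lon}, {lat})"
        )
    if best != (row, col):
        logger.info("snapped site at (%.3f, %.3f) to sea cell %s", lon, lat, best)
    return best


def least_cost_distance(
    graph: nx.Graph,
    grid: SeascapeGrid,
    site_table: pd.DataFrame,
    snap_radius: int = 2,
) -> PairwiseMatrix:
    """Shortest in-water distance (km) between all site pairs.

    Sites in different connected components get ``inf`` (flagged).  A site
    farther than the snap radius from any sea cell raises an error naming it.
    """
    cells = {}
    for _, row in site_table.iterrows():
        try:
            cells[row["site_id"]] = snap_to_sea(
                grid, row["lon"], row["lat"], snap_radius
            )
        except ValueError as exc:
            raise ValueError(f"site {row['site_id']!r}: {exc}") from exc
    site_ids = list(site_table["site_id"])
    n = len(site_ids)
    vals = np.zeros((n, n))
    for i, sid in enumerate(site_ids):
        lengths = nx.single_source_dijkstra_path_length(
            graph, cells[sid], weight="weight"
        )
        for j in range(i + 1, n):
            d = lengths.get(cells[site_ids[j]], np.inf)
            if cells[sid] == cells[site_ids[j]]:
                d = 0.0
            vals[i, j] = vals[j, i] = d
    return PairwiseMatrix(site_ids=site_ids, values=vals, metric=DISTANCE_METRIC)
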