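"""Resistance surfaces and least-cost connectivity between units.

Resistance is an inverse transform of habitat suitability; accumulated
costs are shortest paths on the 8-neighbour cell graph with edge weight
mean(endpoint resistances) x step length (cell size, x sqrt(2) on
diagonals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import LineString
from shapely.geometry.base import BaseGeometry

from .raster import Raster

SQRT2 = float(np.sqrt(2.0))


@dataclass
class ResistanceSurface:
    values: np.ndarray  # movement-cost multipliers in [1, r_max]
    cell_km: float
    origin: tuple[float, float]
    r_max: float

    def as_raster(self) -> Raster:
        return Raster(self.values, self.cell_km, self.origin)


@dataclass
class CostMatrix:
    unit_ids: list[str]
    costs: np.ndarray  # cost-km units; inf for unreachable pairs
    paths: dict[tuple[str, str], LineString | None] = field(default_factory=dict)


def resistance_from_suitability(
    raster: Raster, r_max: float = 100.0, form: str = "linear"
) -> ResistanceSurface:
    """Inverse suitability-to-resistance transform.

    ``linear`` (default): r = 1 + (1 - s)(r_max - 1).  ``reciprocal``:
    r = clip(1/s, 1, r_max).  NoData cells get r_max.
    """
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    s = raster.values
    if form == "linear":
        r = 1.0 + (1.0 - s) * (r_max - 1.0)
    elif form == "reciprocal":
        with np.errstate(divide="ignore"):
            r = np.clip(1.0 / s, 1.0, r_max)
    else:
        raise ValueError(f"unknown resistance form {form!r}")
    r = np.where(np.isfinite(s), r, r_max)
    return ResistanceSurface(r, raster.cell_km, raster.origin, r_max)


def _grid_graph(surface: ResistanceSurface):
    """Sparse symmetric 8-neighbour graph over the resistance grid."""
    r = surface.values
    nrow, ncol = r.shape
    n = nrow * ncol
    idx = np.arange(n).reshape(nrow, ncol)
    rows, cols, data = [], [], []
    steps = [
        ((0, 1), 1.0),
        ((1, 0), 1.0),
        ((1, 1), SQRT2),
        ((1, -1), SQRT2),
    ]
    for (dr, dc), scale in steps:
        a0, a1, w0, w1 = idx, idx, r, r
        if dr > 0:
            a0, a1 = a0[:-dr, :], a1[dr:, :]
            w0, w1 = w0[:-dr, :], w1[dr:, :]
        if dc > 0:
            a0, a1 = a0[:, :-dc], a1[:, dc:]
            w0, w1 = w0[:, :-dc], w1[:, dc:]
        elif dc < 0:
            a0, a1 = a0[:, -dc:], a1[:, :dc]
            w0, w1 = w0[:, -dc:], w1[:, :dc]
        weight = 0.5 * (w0 + w1) * surface.cell_km * scale
        rows.append(a0.ravel())
        cols.append(a1.ravel())
        data.append(weight.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    g = coo_matrix((data, (rows, cols)), shape=(n, n))
    return (g + g.T).tocsr()


def _unit_cell_indices(surface: ResistanceSurface, geom: BaseGeometry) -> np.ndarray:
    """Flat indices of cells whose centre the unit polygon covers (nearest
    cell centre as fallback for slivers)."""
    rast = surface.as_raster()
    X, Y = rast.cell_centers()
    inside = shapely.intersects_xy(geom, X.ravel(), Y.ravel())
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        cx, cy = geom.centroid.x, geom.centroid.y
        d2 = (X.ravel() - cx) ** 2 + (Y.ravel() - cy) ** 2
        idx = np.array([int(np.argmin(d2))])
    return idx


def cost_distance(
    surface: ResistanceSurface, source: BaseGeometry | np.ndarray
) -> np.ndarray:
    """Accumulated least cost from the source to every cell (grid-shaped).

    ``source`` is a polygon/multipolygon or a boolean mask over the grid.
    Source cells have cost 0.
    """
    if isinstance(source, np.ndarray):
        if source.shape != surface.values.shape:
            raise ValueError("source mask shape must match the grid")
        src = np.flatnonzero(source.ravel())
    else:
        xmin, ymin, xmax, ymax = surface.as_raster().extent
        gxmin, gymin, gxmax, gymax = source.bounds
        if gxmax < xmin or gxmin > xmax or gymax < ymin or gymin > ymax:
            raise ValueError("source lies outside the grid")
        src = _unit_cell_indices(surface, source)
    if src.size == 0:
        raise ValueError("source selects no grid cells")
    graph = _grid_graph(surface)
    dist = dijkstra(graph, directed=False, indices=src, min_only=True)
    return dist.reshape(surface.values.shape)


def _backtrack_path(
    surface: ResistanceSurface, predecessors: np.ndarray, target: int
) -> LineString | None:
    chain = [target]
    node = target
    while predecessors[node] >= 0:
        node = int(predecessors[node])
        chain.append(node)
    if len(chain) < 2:
        return None
    rast = surface.as_raster()
    nrow, ncol = rast.shape
    x0, y0 = rast.origin
    pts = []
    for flat in chain:
        rr, cc = divmod(flat, ncol)
        pts.append(
            (x0 + (cc + 0.5) * rast.cell_km, y0 + (nrow - 1 - rr + 0.5) * rast.cell_km)
        )
    return LineString(pts)


def least_cost_linkages(
    surface: ResistanceSurface,
    units: list[tuple[str, BaseGeometry]],
) -> CostMatrix:
    """Pairwise least accumulated costs between unit boundary cells.

    Touching or overlapping units (sharing a grid cell) have cost 0.
    Unreachable pairs get cost inf and no path.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 units")
    ids = [u for u, _ in units]
    cell_sets = [_unit_cell_indices(surface, g) for _, g in units]
    n = len(units)
    costs = np.zeros((n, n))
    paths: dict[tuple[str, str], LineString | None] = {}
    graph = _grid_graph(surface)
    for i in range(n - 1):
        dist, pred, _sources = dijkstra(
            graph, directed=False, indices=cell_sets[i], min_only=True,
            return_predecessors=True,
        )
        for j in range(i + 1, n):
            shared = np.intersect1d(cell_sets[i], cell_sets[j])
            if shared.size:
                costs[i, j] = costs[j, i] = 0.0
                paths[(ids[i], ids[j])] = None
                continue
            dj = dist[cell_sets[j]]
            best = int(np.argmin(dj))
            c = float(dj[best])
            costs[i, j] = costs[j, i] = c
            if np.isinf(c):
                paths[(ids[i], ids[j])] = None
            else:
                paths[(ids[i], ids[j])] = _backtrack_path(
                    surface, pred, int(cell_sets[j][best])
                )
    return CostMatrix(unit_ids=ids, costs=costs, paths=paths)
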