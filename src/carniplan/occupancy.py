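"""Habitat fragments and record-based occupancy labelling.

Suitable cells of the class map are split by roads (any cell a road
polyline intersects becomes a barrier), grouped into 4-connected
components, polygonized, and labelled occupied (AJO), potentially occupied
(APJO) or empty using a fixed search radius around records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point
from shapely.geometry.base import BaseGeometry

from .raster import ClassMap

AJO = "AJO"
APJO = "APJO"
EMPTY = "empty"

SIZE_CLASSES = ("<100", "100-1000", ">1000")

#: 4-connectivity structuring element (no diagonal leaking across roads)
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class HabitatFragment:
    id: int
    geometry: BaseGeometry
    area_km2: float
    good_area_km2: float

    def __post_init__(self) -> None:
        if self.good_area_km2 > self.area_km2 + 1e-9:
            raise ValueError("good_area_km2 cannot exceed area_km2")

    @property
    def size_class(self) -> str:
        if self.area_km2 < 100:
            return SIZE_CLASSES[0]
        if self.area_km2 <= 1000:
            return SIZE_CLASSES[1]
        return SIZE_CLASSES[2]


@dataclass
class OccupancyLabel:
    fragment_id: int
    label: str
    supporting_record_ids: list[int] = field(default_factory=list)


def rasterize_lines(class_map: ClassMap, lines: list[LineString]) -> np.ndarray:
    """Boolean mask of cells intersected by any polyline (exact, vectorized)."""
    nrow, ncol = class_map.values.shape
    mask = np.zeros((nrow, ncol), dtype=bool)
    if not lines:
        return mask
    c = class_map.cell_km
    x0, y0 = class_map.origin
    for line in lines:
        xmin, ymin, xmax, ymax = line.bounds
        c0 = max(int(np.floor((xmin - x0) / c)), 0)
        c1 = min(int(np.floor((xmax - x0) / c)), ncol - 1)
        rlo = max(int(np.floor((ymin - y0) / c)), 0)
        rhi = min(int(np.floor((ymax - y0) / c)), nrow - 1)
        if c0 > c1 or rlo > rhi:
            continue
        cols, rows_s = np.meshgrid(np.arange(c0, c1 + 1), np.arange(rlo, rhi + 1))
        bx0 = x0 + cols * c
        by0 = y0 + rows_s * c
        boxes = shapely.box(bx0.ravel(), by0.ravel(), (bx0 + c).ravel(), (by0 + c).ravel())
        hit = shapely.intersects(line, boxes).reshape(cols.shape)
        rr = nrow - 1 - rows_s[hit]  # south-up index -> row 0 = north
        mask[rr, cols[hit]] = True
    return mask


def _cells_to_polygon(rows: np.ndarray, cols: np.ndarray, class_map: ClassMap) -> BaseGeometry:
    nrow = class_map.values.shape[0]
    c = class_map.cell_km
    x0, y0 = class_map.origin
    bx0 = x0 + cols * c
    by0 = y0 + (nrow - 1 - rows) * c
    boxes = shapely.box(bx0, by0, bx0 + c, by0 + c)
    return shapely.unary_union(boxes)


def extract_fragments(
    class_map: ClassMap, roads: list[LineString] | None = None
) -> list[HabitatFragment]:
    """Road-split suitable habitat as 4-connected components."""
    suitable = class_map.suitable_mask()
    if roads:
        suitable = suitable & ~rasterize_lines(class_map, roads)
    labels, n = ndimage.label(suitable, structure=_STRUCTURE_4)
    cell_area = class_map.cell_km**2
    good = class_map.good_mask() & suitable
    fragments = []
    for fid in range(1, n + 1):
        rows, cols = np.nonzero(labels == fid)
        geom = _cells_to_polygon(rows, cols, class_map)
        fragments.append(
            HabitatFragment(
                id=fid,
                geometry=geom,
                area_km2=float(rows.size * cell_area),
                good_area_km2=float(np.count_nonzero(good[rows, cols]) * cell_area),
            )
        )
    return fragments


def _record_points(records: pd.DataFrame) -> list[Point]:
    return [Point(x, y) for x, y in zip(records["x_km"], records["y_km"])]


def median_outside_distance(
    records: pd.DataFrame, fragments: list[HabitatFragment]
) -> float:
    """Median distance from records lying outside all fragments to the
    nearest fragment boundary (km).  Records inside any fragment are
    excluded; raises if none lies outside."""
    if not fragments:
        raise ValueError("no fragments supplied")
    dists = []
    for pt in _record_points(records):
        d = min(frag.geometry.distance(pt) for frag in fragments)
        if d > 0:
            dists.append(d)
    if not dists:
        raise ValueError(
            "no records outside fragments; supply the occupancy radius in config"
        )
    return float(np.median(dists))


def classify_occupancy(
    fragments: list[HabitatFragment],
    records: pd.DataFrame,
    radius_km: float = 1.7,
) -> list[OccupancyLabel]:
    """Two-pass labelling.

    Pass 1 (AJO): a record inside the fragment or strictly closer than
    ``radius_km`` to it.  Pass 2 (APJO): a record-free fragment strictly
    closer than ``radius_km`` to an AJO fragment.  APJO does not chain.
    """
    if radius_km < 0:
        raise ValueError("radius_km must be >= 0")
    pts = _record_points(records)
    labels: dict[int, OccupancyLabel] = {}
    ajo_geoms = []
    for frag in fragments:
        support = [
            i
            for i, pt in enumerate(pts)
            if frag.geometry.covers(pt) or frag.geometry.distance(pt) < radius_km
        ]
        if support:
            labels[frag.id] = OccupancyLabel(frag.id, AJO, support)
            ajo_geoms.append(frag.geometry)
    for frag in fragments:
        if frag.id in labels:
            continue
        near_ajo = any(frag.geometry.distance(g) < radius_km for g in ajo_geoms)
        labels[frag.id] = OccupancyLabel(frag.id, APJO if near_ajo else EMPTY)
    return [labels[f.id] for f in fragments]


def occupancy_summary(
    fragments: list[HabitatFragment], labels: list[OccupancyLabel]
) -> pd.DataFrame:
    """Counts and areas per size class and occupancy label."""
    by_id = {l.fragment_id: l.label for l in labels}
    missing = [f.id for f in fragments if f.id not in by_id]
    if missing:
        raise ValueError(f"labels missing for fragments {missing}")
    rows = []
    for size_class in SIZE_CLASSES:
        in_class = [f for f in fragments if f.size_class == size_class]
        for lab in (AJO, APJO, EMPTY):
            sel = [f for f in in_class if by_id[f.id] == lab]
            rows.append(
                {
                    "size_class": size_class,
                    "label": lab,
                    "n_fragments": len(sel),
                    "area_km2": float(sum(f.area_km2 for f in sel)),
                }
            )
    return pd.DataFrame(rows)


def habitat_ratios(
    suitable_class_areas_km2: dict[str, float],
    ajo_area_km2: float,
    apjo_area_km2: float,
) -> dict[str, float]:
    """Occupied / potential / empty percentages of the total suitable area.

    ``suitable_class_areas_km2`` holds the areas of the marginal, medium and
    high classes.  Percentages are rounded to one decimal, as printed in
    report tables.
    """
    keys = ("marginal", "medium", "high")
    missing = [k for k in keys if k not in suitable_class_areas_km2]
    if missing:
        raise ValueError(f"missing suitability class areas: {missing}")
    total = float(sum(suitable_class_areas_km2[k] for k in keys))
    if total <= 0:
        raise ValueError("total suitable area must be positive")
    occupied = 100.0 * ajo_area_km2 / total
    potential = 100.0 * apjo_area_km2 / total
    empty = 100.0 * (total - ajo_area_km2 - apjo_area_km2) / total
    return {
        "total_suitable_km2": total,
        "occupied_pct": round(occupied, 1),
        "potential_pct": round(potential, 1),
        "empty_pct": round(empty, 1),
    }
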