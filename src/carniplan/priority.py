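"""Conservation-unit grouping, classification and population aggregation.

Occupied fragments are grouped by single-linkage distance clustering into
candidate units; each unit is classified as JCU Type I / Type II, PJCU or
small fragment from its evidence (sex confirmation, population estimate or
carrying capacity, good-condition habitat area).  Record-free fragments are
rated as potential expansion or future core areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .occupancy import AJO, APJO, HabitatFragment, OccupancyLabel

JCU_I = "JCU_I"
JCU_II = "JCU_II"
PJCU = "PJCU"
SMALL_FRAGMENT = "small_fragment"
EXPANSION = "expansion"
CORE = "core"
OTHER = "other"


@dataclass
class ClassRules:
    pop_threshold: int = 50  # adults for Type I
    good_area_threshold_km2: float = 230.0  # smallest JCU's good habitat
    reference_density_per_100km2: float = 1.0  # capacity rule density
    grouping_radius_km: float = 15.0


@dataclass
class UnitEvidence:
    unit_id: str
    member_fragment_ids: list[int] = field(default_factory=list)
    total_area_km2: float = 0.0
    ajo_area_km2: float = 0.0
    apjo_area_km2: float = 0.0
    good_area_km2: float = 0.0
    both_sexes_confirmed: bool = False
    population_estimate: tuple[int, int, int] | None = None
    name: str | None = None
    geometry: object | None = None

    def __post_init__(self) -> None:
        # tolerance admits km2-rounded published tables
        tol = 1e-6 + 1e-3 * max(self.total_area_km2, 1.0)
        if abs(self.total_area_km2 - (self.ajo_area_km2 + self.apjo_area_km2)) > tol:
            raise ValueError("total area must equal AJO + APJO areas")


@dataclass
class UnitClassification:
    unit_id: str
    label: str
    rationale: list[str] = field(default_factory=list)


def group_fragments(
    fragments: list[HabitatFragment],
    labels: list[OccupancyLabel],
    grouping_radius_km: float = 15.0,
    forced_merges: list[tuple[int, int]] | None = None,
    both_sexes_by_fragment: dict[int, bool] | None = None,
    estimates_by_fragment: dict[int, tuple[int, int, int]] | None = None,
) -> list[UnitEvidence]:
    """Single-linkage clustering of AJO/APJO fragments.

    Fragments whose boundary-to-boundary distance is strictly below
    ``grouping_radius_km`` join the same unit; ``forced_merges`` pairs are
    joined regardless of distance.
    """
    if grouping_radius_km < 0:
        raise ValueError("grouping_radius_km must be >= 0")
    lab = {l.fragment_id: l.label for l in labels}
    members = [f for f in fragments if lab.get(f.id) in (AJO, APJO)]
    if not members:
        return []
    idx = {f.id: i for i, f in enumerate(members)}
    parent = list(range(len(members)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if members[i].geometry.distance(members[j].geometry) < grouping_radius_km:
                union(i, j)
    for a, b in forced_merges or []:
        if a in idx and b in idx:
            union(idx[a], idx[b])

    groups: dict[int, list[HabitatFragment]] = {}
    for i, f in enumerate(members):
        groups.setdefault(find(i), []).append(f)

    both_sexes_by_fragment = both_sexes_by_fragment or {}
    estimates_by_fragment = estimates_by_fragment or {}
    units = []
    for k, (_, frs) in enumerate(sorted(groups.items())):
        ajo_area = sum(f.area_km2 for f in frs if lab[f.id] == AJO)
        apjo_area = sum(f.area_km2 for f in frs if lab[f.id] == APJO)
        ests = [estimates_by_fragment[f.id] for f in frs if f.id in estimates_by_fragment]
        est = tuple(int(sum(e[c] for e in ests)) for c in range(3)) if ests else None
        geom = None
        try:
            from shapely.ops import unary_union

            geom = unary_union([f.geometry for f in frs])
        except Exception:
            pass
        units.append(
            UnitEvidence(
                unit_id=f"U{k + 1:02d}",
                member_fragment_ids=sorted(f.id for f in frs),
                total_area_km2=float(ajo_area + apjo_area),
                ajo_area_km2=float(ajo_area),
                apjo_area_km2=float(apjo_area),
                good_area_km2=float(sum(f.good_area_km2 for f in frs)),
                both_sexes_confirmed=any(
                    both_sexes_by_fragment.get(f.id, False) for f in frs
                ),
                population_estimate=est,
                geometry=geom,
            )
        )
    return units


def classify_unit(ev: UnitEvidence, rules: ClassRules | None = None) -> UnitClassification:
    """Rule-based unit label.

    Both sexes confirmed: Type I when the point population estimate reaches
    the threshold OR the unit's carrying capacity (AJO area x reference
    density) does; otherwise Type II.  Without both sexes: PJCU when
    good-condition habitat reaches the area threshold, else small fragment.
    """
    rules = rules or ClassRules()
    rationale: list[str] = []
    if ev.both_sexes_confirmed:
        capacity = ev.ajo_area_km2 * rules.reference_density_per_100km2 / 100.0
        if ev.population_estimate is None:
            rationale.append("no population estimate; classified by capacity only")
        point = ev.population_estimate[0] if ev.population_estimate else None
        if point is not None and point >= rules.pop_threshold:
            rationale.append(f"estimated population {point} >= {rules.pop_threshold}")
            return UnitClassification(ev.unit_id, JCU_I, rationale)
        if capacity >= rules.pop_threshold:
            rationale.append(
                f"capacity {capacity:.1f} >= {rules.pop_threshold} "
                f"(AJO {ev.ajo_area_km2:.0f} km2 x {rules.reference_density_per_100km2}/100 km2)"
            )
            return UnitClassification(ev.unit_id, JCU_I, rationale)
        rationale.append(f"population below {rules.pop_threshold}")
        return UnitClassification(ev.unit_id, JCU_II, rationale)
    if ev.good_area_km2 >= rules.good_area_threshold_km2:
        rationale.append(
            f"good habitat {ev.good_area_km2:.0f} km2 >= {rules.good_area_threshold_km2:.0f}"
        )
        return UnitClassification(ev.unit_id, PJCU, rationale)
    rationale.append(
        f"good habitat {ev.good_area_km2:.0f} km2 < {rules.good_area_threshold_km2:.0f}"
    )
    return UnitClassification(ev.unit_id, SMALL_FRAGMENT, rationale)


def classify_empty_areas(
    empty_fragments: list[HabitatFragment],
    units: list[tuple[str, object]],
    radius_km: float = 15.0,
    core_area_threshold_km2: float = 230.0,
) -> dict[int, str]:
    """Label record-free fragments.

    ``units`` holds (label, geometry) pairs for classified JCU/PJCU units.
    Expansion: within ``radius_km`` of a JCU or PJCU; else core when
    good-condition habitat reaches the threshold; else other.
    """
    unit_geoms = [g for lbl, g in units if lbl in (JCU_I, JCU_II, PJCU) and g is not None]
    out = {}
    for frag in empty_fragments:
        if any(frag.geometry.distance(g) < radius_km for g in unit_geoms):
            out[frag.id] = EXPANSION
        elif frag.good_area_km2 >= core_area_threshold_km2:
            out[frag.id] = CORE
        else:
            out[frag.id] = OTHER
    return out


def aggregate_population(units: list[UnitEvidence]) -> tuple[int, int, int]:
    """Component-wise sum of (point, low, high) over units with estimates."""
    ests = [u.population_estimate for u in units if u.population_estimate is not None]
    if not ests:
        raise ValueError("no unit carries a population estimate")
    return tuple(int(sum(e[c] for e in ests)) for c in range(3))


_RECOMMENDATIONS: dict[str, list[str]] = {
    JCU_I: [
        "Reduce all sources of mortality and poaching of prey.",
        "Maintain connectivity among the main habitat blocks.",
        "Evaluate connectivity with neighbouring units.",
        "Monitor the population.",
    ],
    JCU_II: [
        "Reduce all sources of mortality and poaching of prey.",
        "Monitor the population, with emphasis on genetic diversity.",
    ],
    PJCU: [
        "Evaluate the status of the population.",
        "If a population exists, reduce all sources of mortality and evaluate its main threats.",
        "Evaluate habitat connectivity with neighbouring units.",
    ],
    SMALL_FRAGMENT: [
        "Area too small to maintain a resident population; reduce mortality threats.",
        "Evaluate connectivity with a conservation unit.",
        "Studies of movements through the human-dominated matrix are recommended.",
    ],
}

_ISOLATED_EXTRA = "Evaluate the supplementation of individuals."


def recommend(classification: UnitClassification, isolated: bool = False) -> list[str]:
    """Static label -> management-recommendation lookup."""
    if classification.label not in _RECOMMENDATIONS:
        raise ValueError(f"unknown unit label {classification.label!r}")
    recs = list(_RECOMMENDATIONS[classification.label])
    if isolated and classification.label in (JCU_I, JCU_II):
        recs.append(_ISOLATED_EXTRA)
    return recs


# ---------------------------------------------------------------------------
# Evidence-table fixture support (prioritization-only mode)

UNIT_TABLE_COLUMNS = [
    "name",
    "both_sexes",
    "total_area_km2",
    "ajo_km2",
    "apjo_km2",
    "good_area_km2",
    "pop",
    "pop_lo",
    "pop_hi",
]


def load_unit_table(path: str | Path) -> list[UnitEvidence]:
    """Read a unit-evidence CSV (one row per candidate unit)."""
    df = pd.read_csv(path)
    missing = set(UNIT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"unit table missing columns {sorted(missing)}")
    units = []
    for k, row in df.iterrows():
        est = None
        if not pd.isna(row["pop"]):
            est = (int(row["pop"]), int(row["pop_lo"]), int(row["pop_hi"]))
        units.append(
            UnitEvidence(
                unit_id=f"U{k + 1:02d}",
                name=str(row["name"]),
                total_area_km2=float(row["total_area_km2"]),
                ajo_area_km2=float(row["ajo_km2"]),
                apjo_area_km2=float(row["apjo_km2"]),
                good_area_km2=float(row["good_area_km2"]),
                both_sexes_confirmed=bool(row["both_sexes"]),
                population_estimate=est,
            )
        )
    return units


def unit_area_shares(
    units: list[UnitEvidence], classifications: list[UnitClassification]
) -> dict[str, float]:
    """Percent of the summed unit area contributed by each label (unrounded)."""
    lab = {c.unit_id: c.label for c in classifications}
    total = sum(u.total_area_km2 for u in units)
    if total <= 0:
        raise ValueError("total unit area must be positive")
    shares: dict[str, float] = {}
    for label in (JCU_I, JCU_II, PJCU, SMALL_FRAGMENT):
        area = sum(u.total_area_km2 for u in units if lab.get(u.unit_id) == label)
        shares[label] = 100.0 * area / total
    return shares
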