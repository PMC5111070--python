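"""End-to-end orchestration and input validation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import abundance, connectivity, io, occupancy, priority, suitability, synth
from .config import PipelineConfig, bundled_data_path
from .raster import read_ascii_grid, validate_suitability, write_ascii_grid


@dataclass
class ValidationReport:
    checked: list[str] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_inputs(paths: dict[str, str | Path]) -> ValidationReport:
    """Schema/range checks for the standard input files.

    Recognized keys: suitability (ASCII grid), records, traps, detections
    (CSV), roads (GeoJSON).  Failures are collected, not raised.
    """
    rep = ValidationReport()
    raster = None
    if "suitability" in paths:
        rep.checked.append("suitability")
        try:
            raster = read_ascii_grid(paths["suitability"])
            validate_suitability(raster)
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            rep.failures.append(f"suitability: {exc}")
    if "records" in paths:
        rep.checked.append("records")
        try:
            rec = io.read_records(paths["records"])
            if raster is not None and len(rec):
                outside = ~raster.contains(rec["x_km"].to_numpy(), rec["y_km"].to_numpy())
                for i in np.flatnonzero(outside):
                    rep.failures.append(f"records: row {i} outside raster extent")
        except Exception as exc:  # noqa: BLE001
            rep.failures.append(f"records: {exc}")
    traps = None
    if "traps" in paths:
        rep.checked.append("traps")
        try:
            traps = io.read_traps(paths["traps"])
            if traps["trap_id"].duplicated().any():
                rep.failures.append("traps: duplicated trap_id")
        except Exception as exc:  # noqa: BLE001
            rep.failures.append(f"traps: {exc}")
    if "detections" in paths:
        rep.checked.append("detections")
        try:
            det = io.read_detections(paths["detections"])
            if (det["occasion"] < 1).any():
                rep.failures.append("detections: occasion indices must be >= 1")
            bad_sex = set(det["sex"]) - {"F", "M", "U"}
            if bad_sex:
                rep.failures.append(f"detections: unknown sex codes {sorted(bad_sex)}")
            bad_age = set(det["age"]) - {"adult", "cub"}
            if bad_age:
                rep.failures.append(f"detections: unknown age codes {sorted(bad_age)}")
            if traps is not None:
                unknown = set(det["trap_id"]) - set(traps["trap_id"])
                for t in sorted(map(str, unknown)):
                    rep.failures.append(f"detections: unknown trap_id {t}")
        except Exception as exc:  # noqa: BLE001
            rep.failures.append(f"detections: {exc}")
    if "roads" in paths:
        rep.checked.append("roads")
        try:
            geoms, _ = io.geojson_to_geometries(paths["roads"])
            non_lines = [g.geom_type for g in geoms if g.geom_type != "LineString"]
            if non_lines:
                rep.failures.append(f"roads: non-LineString geometries {non_lines}")
        except Exception as exc:  # noqa: BLE001
            rep.failures.append(f"roads: {exc}")
    return rep


def run_units_table(
    units_csv: str | Path | None = None, config: PipelineConfig | None = None
) -> dict:
    """Prioritization-only mode: classify a unit-evidence table and
    aggregate population estimates (no rasters required)."""
    config = config or PipelineConfig()
    path = Path(units_csv) if units_csv else bundled_data_path("priority_units.csv")
    units = priority.load_unit_table(path)
    rules = priority.ClassRules(
        pop_threshold=config.pop_threshold,
        good_area_threshold_km2=config.good_area_threshold_km2,
        reference_density_per_100km2=config.reference_density_per_100km2,
        grouping_radius_km=config.grouping_radius_km,
    )
    classifications = [priority.classify_unit(u, rules) for u in units]
    shares = priority.unit_area_shares(units, classifications)
    agg = priority.aggregate_population(units)
    label_counts: dict[str, int] = {}
    for c in classifications:
        label_counts[c.label] = label_counts.get(c.label, 0) + 1
    return {
        "mode": "units_table",
        "units": [
            {
                "unit_id": u.unit_id,
                "name": u.name,
                "label": c.label,
                "total_area_km2": u.total_area_km2,
                "ajo_area_km2": u.ajo_area_km2,
                "apjo_area_km2": u.apjo_area_km2,
                "population_estimate": u.population_estimate,
                "rationale": c.rationale,
                "recommendations": priority.recommend(c),
            }
            for u, c in zip(units, classifications)
        ],
        "label_counts": label_counts,
        "area_shares_pct": shares,
        "aggregate_population": list(agg),
    }


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> dict:
    """Synthetic end-to-end run: landscape -> suitability evaluation ->
    occupancy -> SECR abundance -> prioritization -> connectivity.

    Deterministic per (config, seed).  Returns the report dict; artifacts
    are written under ``out_dir`` when given.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    spec = synth.LandscapeSpec(
        extent_km=config.extent_km,
        cell_km=config.cell_km,
        autocorrelation_range_km=config.autocorrelation_range_km,
        road_count=config.road_count,
        seed=config.seed,
    )
    raster, roads = synth.generate_landscape(spec)
    records = synth.sample_presences(raster, config.n_presences, rng)

    thinned = suitability.thin_records(records, config.thinning_cell_area_km2, rng)
    cv = suitability.cross_validate(
        raster,
        thinned,
        train_fraction=config.train_fraction,
        n_replicates=config.n_replicates,
        n_background=config.n_background,
        seed=rng,
    )
    threshold = (
        config.decision_threshold
        if config.decision_threshold is not None
        else min(cv["threshold"], config.class_bounds[0] - 1e-6)
    )
    class_map = suitability.reclassify(raster, threshold, config.class_bounds)

    fragments = occupancy.extract_fragments(class_map, roads)
    if config.occupancy_radius_km is not None:
        radius = config.occupancy_radius_km
    else:
        try:
            radius = occupancy.median_outside_distance(records, fragments)
        except ValueError:
            radius = config.fallback_radius_km
    labels = occupancy.classify_occupancy(fragments, records, radius)
    summary = occupancy.occupancy_summary(fragments, labels)

    # --- abundance: simulate + fit one camera-trap survey in the largest AJO
    lab_by_id = {l.fragment_id: l.label for l in labels}
    ajo_frags = [f for f in fragments if lab_by_id[f.id] == occupancy.AJO]
    abundance_report: dict = {"surveyed_fragment": None}
    estimates_by_fragment: dict[int, tuple[int, int, int]] = {}
    both_sexes: dict[int, bool] = {}
    if ajo_frags:
        target = max(ajo_frags, key=lambda f: f.area_km2)
        cx, cy = target.geometry.centroid.x, target.geometry.centroid.y
        half = 10.0
        survey_box = box(cx - half, cy - half, cx + half, cy + half)
        truth = synth.SecrTruth(
            density_true=config.reference_density_per_100km2,
            p0_true=0.15,
            sigma_true=1.5,
            n_occasions=40,
            trap_spacing_km=1.5,
        )
        data = synth.simulate_secr(truth, survey_box, rng)
        scfg = abundance.SecrConfig(
            state_space_buffer_km=min(config.secr.state_space_buffer_km, 6.0),
            state_space_cell_km=config.secr.state_space_cell_km,
            M=config.secr.M,
            n_iter=config.secr.n_iter,
            n_burn=config.secr.n_burn,
            thin=config.secr.thin,
            seed=config.seed,
            min_individuals=config.secr.min_individuals,
        )
        try:
            fit = abundance.fit_secr(data, scfg)
            est = abundance.population_from_fit(fit)
            estimates_by_fragment[target.id] = est
            abundance_report = {
                "surveyed_fragment": target.id,
                "path": "secr",
                "n_detected": fit.n_detected,
                "density": fit.summary["density"],
                "population_estimate": list(est),
                "geweke": fit.geweke,
            }
        except abundance.InsufficientDataError as exc:
            try:
                ns = abundance.nonspatial_fit(data, config.secr.nonspatial_buffer_km)
                est = abundance.population_from_fit(ns)
                estimates_by_fragment[target.id] = est
                abundance_report = {
                    "surveyed_fragment": target.id,
                    "path": "nonspatial",
                    "reason": str(exc),
                    "n_hat": ns.n_hat,
                    "density_per_100km2": ns.density_per_100km2,
                    "population_estimate": list(est),
                }
            except (abundance.InsufficientDataError, ValueError) as exc2:
                abundance_report = {
                    "surveyed_fragment": target.id,
                    "path": "none",
                    "reason": f"{exc}; fallback failed: {exc2}",
                }
        both_sexes[target.id] = {"F", "M"} <= set(data.sex)
        if out:
            data.to_csv(out / "traps.csv", out / "detections.csv")

    units = priority.group_fragments(
        fragments,
        labels,
        grouping_radius_km=config.grouping_radius_km,
        both_sexes_by_fragment=both_sexes,
        estimates_by_fragment=estimates_by_fragment,
    )
    rules = priority.ClassRules(
        pop_threshold=config.pop_threshold,
        good_area_threshold_km2=config.good_area_threshold_km2,
        reference_density_per_100km2=config.reference_density_per_100km2,
        grouping_radius_km=config.grouping_radius_km,
    )
    classifications = [priority.classify_unit(u, rules) for u in units]
    empty_frags = [f for f in fragments if lab_by_id[f.id] == occupancy.EMPTY]
    empty_labels = priority.classify_empty_areas(
        empty_frags,
        [(c.label, u.geometry) for u, c in zip(units, classifications)],
        radius_km=config.grouping_radius_km,
        core_area_threshold_km2=config.good_area_threshold_km2,
    )
    try:
        aggregate = list(priority.aggregate_population(units))
    except ValueError:
        aggregate = None

    conn_report = None
    if len(units) >= 2:
        surface = connectivity.resistance_from_suitability(
            raster, config.r_max, config.resistance_form
        )
        cm = connectivity.least_cost_linkages(
            surface, [(u.unit_id, u.geometry) for u in units]
        )
        conn_report = {
            "unit_ids": cm.unit_ids,
            "cost_matrix": [
                [None if np.isinf(v) else round(float(v), 6) for v in row]
                for row in cm.costs
            ],
        }
        if out:
            pd.DataFrame(cm.costs, index=cm.unit_ids, columns=cm.unit_ids).to_csv(
                out / "cost_matrix.csv"
            )
            pairs = [(k, p) for k, p in cm.paths.items() if p is not None]
            if pairs:
                io.geometries_to_geojson(
                    [p for _, p in pairs],
                    [{"from": a, "to": b} for (a, b), _ in pairs],
                    out / "least_cost_paths.geojson",
                )

    report = {
        "mode": "synthetic",
        "seed": config.seed,
        "suitability": {
            "cross_validation": cv,
            "threshold": threshold,
            "class_areas_km2": class_map.class_areas_km2(),
        },
        "occupancy": {
            "radius_km": radius,
            "n_fragments": len(fragments),
            "summary": summary.to_dict(orient="records"),
        },
        "abundance": abundance_report,
        "units": [
            {
                "unit_id": u.unit_id,
                "label": c.label,
                "member_fragments": u.member_fragment_ids,
                "total_area_km2": u.total_area_km2,
                "ajo_area_km2": u.ajo_area_km2,
                "apjo_area_km2": u.apjo_area_km2,
                "good_area_km2": u.good_area_km2,
                "population_estimate": (
                    list(u.population_estimate) if u.population_estimate else None
                ),
            }
            for u, c in zip(units, classifications)
        ],
        "empty_area_labels": {str(k): v for k, v in sorted(empty_labels.items())},
        "aggregate_population": aggregate,
        "connectivity": conn_report,
    }

    if out:
        write_ascii_grid(raster, out / "suitability.asc")
        write_ascii_grid(class_map.as_raster(), out / "classmap.asc")
        io.write_records(records, out / "records.csv")
        io.geometries_to_geojson(roads, None, out / "roads.geojson")
        io.geometries_to_geojson(
            [f.geometry for f in fragments],
            [
                {
                    "id": f.id,
                    "area_km2": f.area_km2,
                    "good_area_km2": f.good_area_km2,
                    "label": lab_by_id[f.id],
                }
                for f in fragments
            ],
            out / "fragments.geojson",
        )
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
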