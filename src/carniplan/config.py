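"""Pipeline configuration with published default thresholds."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path


def bundled_data_path(name: str) -> Path:
    """Path to a packaged data file (unit-evidence table, regional areas)."""
    return Path(str(resources.files("carniplan").joinpath("data", name)))


@dataclass
class SecrSettings:
    state_space_buffer_km: float = 15.0
    state_space_cell_km: float = 1.0
    n_iter: int = 52_000
    n_burn: int = 2_000
    thin: int = 10
    min_individuals: int = 6
    M: int | None = None
    nonspatial_buffer_km: float = 5.8  # mean home-range radius for buffer union


@dataclass
class PipelineConfig:
    """All module thresholds plus the seed; JSON round-trippable."""

    seed: int = 1
    # suitability post-processing
    thinning_cell_area_km2: float = 144.0
    train_fraction: float = 0.7
    n_replicates: int = 10
    class_bounds: tuple[float, float] = (0.5, 0.75)
    decision_threshold: float | None = None  # None: select max sens+spec
    n_background: int = 10_000
    # occupancy
    occupancy_radius_km: float | None = None  # None: median outside distance
    fallback_radius_km: float = 1.7
    # prioritization
    grouping_radius_km: float = 15.0
    pop_threshold: int = 50
    good_area_threshold_km2: float = 230.0
    reference_density_per_100km2: float = 1.0
    # connectivity
    r_max: float = 100.0
    resistance_form: str = "linear"
    # abundance
    secr: SecrSettings = field(default_factory=SecrSettings)
    # synthetic landscape (run-all simulate mode)
    extent_km: float = 60.0
    cell_km: float = 1.0
    autocorrelation_range_km: float = 6.0
    road_count: int = 2
    n_presences: int = 120
    # provenance only: upstream suitability-model settings are not refit here
    upstream_model_notes: str = "convergence 1e-5, 500 iterations, 10000 background points"

    def __post_init__(self) -> None:
        positives = {
            "thinning_cell_area_km2": self.thinning_cell_area_km2,
            "grouping_radius_km": self.grouping_radius_km,
            "pop_threshold": self.pop_threshold,
            "good_area_threshold_km2": self.good_area_threshold_km2,
            "reference_density_per_100km2": self.reference_density_per_100km2,
            "r_max": self.r_max,
            "fallback_radius_km": self.fallback_radius_km,
        }
        for name, v in positives.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive (got {v})")
        self.class_bounds = tuple(self.class_bounds)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, src: str | Path) -> "PipelineConfig":
        p = Path(src)
        payload = json.loads(p.read_text() if p.exists() else str(src))
        secr = payload.pop("secr", {})
        payload["secr"] = SecrSettings(**secr) if isinstance(secr, dict) else secr
        return cls(**payload)
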