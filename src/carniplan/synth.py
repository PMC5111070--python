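"""Synthetic landscapes, presence records and capture histories.

Everything is a pure function of (spec, seed): pass either an integer seed
or a ``numpy.random.Generator``.  No global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Polygon

from .capture import CaptureData
from .raster import Raster


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a synthetic study rectangle."""

    extent_km: float = 100.0
    cell_km: float = 1.0
    autocorrelation_range_km: float = 10.0
    road_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_km <= 0 or self.cell_km <= 0:
            raise ValueError("extent_km and cell_km must be positive")
        n = self.extent_km / self.cell_km
        if abs(n - round(n)) > 1e-9:
            raise ValueError("cell_km must divide extent_km evenly")
        if self.autocorrelation_range_km < 0:
            raise ValueError("autocorrelation_range_km must be >= 0")
        if self.road_count < 0:
            raise ValueError("road_count must be >= 0")

    @property
    def n_cells(self) -> int:
        return round(self.extent_km / self.cell_km)


@dataclass(frozen=True)
class SecrTruth:
    """Known generative parameters for a capture-history simulation."""

    density_true: float = 1.0  # individuals / 100 km^2
    p0_true: float = 0.1  # per-occasion baseline detection probability
    sigma_true: float = 2.0  # half-normal scale, km
    n_occasions: int = 60
    trap_spacing_km: float = 2.0

    def __post_init__(self) -> None:
        if min(self.density_true, self.p0_true, self.sigma_true, self.trap_spacing_km) <= 0:
            if self.p0_true != 0.0:  # p0 = 0 allowed: degenerate no-detection model
                raise ValueError("all SecrTruth parameters must be positive")
        if not 0.0 <= self.p0_true < 1.0:
            raise ValueError("p0_true must lie in [0, 1)")
        if self.n_occasions < 1:
            raise ValueError("n_occasions must be >= 1")


def detection_probability(dist_km: np.ndarray, p0: float, sigma: float) -> np.ndarray:
    """Half-normal per-occasion detection probability at distance d."""
    d = np.asarray(dist_km, dtype=float)
    return p0 * np.exp(-(d**2) / (2.0 * sigma**2))


def generate_landscape(spec: LandscapeSpec) -> tuple[Raster, list[LineString]]:
    """Spatially autocorrelated suitability surface plus roads.

    The field is Gaussian white noise smoothed with a Gaussian kernel whose
    scale equals the declared autocorrelation range, then min-max rescaled
    to [0, 1].  Roads are straight polylines between random points on two
    different edges of the extent.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    field = rng.standard_normal((n, n))
    sigma_cells = spec.autocorrelation_range_km / spec.cell_km
    if sigma_cells > 0:
        field = ndimage.gaussian_filter(field, sigma=sigma_cells, mode="reflect")
    lo, hi = field.min(), field.max()
    if hi > lo:
        field = (field - lo) / (hi - lo)
    else:
        field = np.full_like(field, 0.5)
    raster = Raster(field.astype(float), cell_km=spec.cell_km, origin=(0.0, 0.0))

    roads: list[LineString] = []
    e = spec.extent_km
    for _ in range(spec.road_count):
        side_a, side_b = rng.choice(4, size=2, replace=False)
        pts = []
        for side in (side_a, side_b):
            t = rng.uniform(0.05, 0.95) * e
            pts.append(
                {0: (t, 0.0), 1: (t, e), 2: (0.0, t), 3: (e, t)}[int(side)]
            )
        roads.append(LineString(pts))
    return raster, roads


def sample_presences(
    raster: Raster, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Presence points with cell-choice probability proportional to suitability."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed)
    v = np.nan_to_num(raster.values, nan=0.0).ravel()
    if n == 0:
        return pd.DataFrame(columns=["x_km", "y_km", "date", "source"])
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot sample presences from an all-zero raster")
    flat = rng.choice(v.size, size=n, p=v / total)
    nrow, ncol = raster.shape
    rows, cols = np.unravel_index(flat, (nrow, ncol))
    x0, y0 = raster.origin
    c = raster.cell_km
    x = x0 + (cols + rng.uniform(size=n)) * c
    y = y0 + (nrow - 1 - rows + rng.uniform(size=n)) * c
    return pd.DataFrame(
        {
            "x_km": x,
            "y_km": y,
            "date": "2012-06-01",
            "source": "synthetic",
        }
    )


def build_trap_grid(state_space: Polygon, spacing_km: float, margin_km: float) -> pd.DataFrame:
    """Regular trap grid centred in the state-space bounding box, inset by margin."""
    xmin, ymin, xmax, ymax = state_space.bounds
    w = xmax - xmin - 2 * margin_km
    h = ymax - ymin - 2 * margin_km
    if w < 0 or h < 0:
        raise ValueError("state space too small for trap grid with the required margin")
    nx = int(np.floor(w / spacing_km)) + 1
    ny = int(np.floor(h / spacing_km)) + 1
    ox = xmin + margin_km + (w - (nx - 1) * spacing_km) / 2
    oy = ymin + margin_km + (h - (ny - 1) * spacing_km) / 2
    xs, ys = np.meshgrid(ox + np.arange(nx) * spacing_km, oy + np.arange(ny) * spacing_km)
    return pd.DataFrame(
        {
            "trap_id": [f"T{i:03d}" for i in range(xs.size)],
            "x_km": xs.ravel(),
            "y_km": ys.ravel(),
        }
    )


def _uniform_points_in_polygon(
    poly: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    xmin, ymin, xmax, ymax = poly.bounds
    pts = np.empty((0, 2))
    while pts.shape[0] < n:
        m = max(4 * (n - pts.shape[0]), 16)
        x = rng.uniform(xmin, xmax, m)
        y = rng.uniform(ymin, ymax, m)
        keep = shapely.contains_xy(poly, x, y)
        pts = np.vstack([pts, np.column_stack([x[keep], y[keep]])])
    return pts[:n]


def simulate_secr(
    truth: SecrTruth,
    state_space: Polygon,
    seed: int | np.random.Generator,
    fixed_n: int | None = None,
    centers: np.ndarray | None = None,
    traps: pd.DataFrame | None = None,
) -> CaptureData:
    """Simulate capture histories from the half-normal SECR detection model.

    Individuals number N ~ Poisson(density x area / 100) (or ``fixed_n``),
    with activity centers uniform on the state space (or ``centers``
    override, an (N, 2) array).  Detection of individual i at trap j on each
    occasion is Bernoulli with probability p0 * exp(-d_ij^2 / (2 sigma^2)).
    Only detected individuals appear in the output.
    """
    if state_space is None or state_space.is_empty or state_space.area <= 0:
        raise ValueError("state space must be a non-empty polygon")
    rng = _rng(seed)
    if traps is None:
        traps = build_trap_grid(state_space, truth.trap_spacing_km, 3.0 * truth.sigma_true)

    if centers is not None:
        centers = np.asarray(centers, dtype=float)
        n_real = centers.shape[0]
    else:
        if fixed_n is not None:
            n_real = int(fixed_n)
        else:
            n_real = int(rng.poisson(truth.density_true * state_space.area / 100.0))
        centers = _uniform_points_in_polygon(state_space, n_real, rng)

    txy = traps[["x_km", "y_km"]].to_numpy(dtype=float)
    if n_real == 0:
        det = np.zeros((0, len(traps), truth.n_occasions), dtype=np.int8)
    else:
        d = np.sqrt(((centers[:, None, :] - txy[None, :, :]) ** 2).sum(axis=2))
        p = detection_probability(d, truth.p0_true, truth.sigma_true)
        det = (
            rng.random((n_real, len(traps), truth.n_occasions)) < p[:, :, None]
        ).astype(np.int8)

    seen = det.sum(axis=(1, 2)) > 0
    det = det[seen]
    n_seen = det.shape[0]
    sexes = rng.choice(["F", "M", "U"], size=n_seen, p=[0.45, 0.45, 0.10]).tolist()
    return CaptureData(
        traps=traps,
        n_occasions=truth.n_occasions,
        detections=det,
        individual_ids=[f"IND{i:03d}" for i in range(n_seen)],
        sex=sexes,
        age=["adult"] * n_seen,
        n_realized=n_real,
        density_true=truth.density_true,
    )
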