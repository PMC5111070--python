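"""Post-processing and evaluation of a continuous habitat-suitability raster.

The suitability model itself is produced upstream; this module thins
presence records, selects a decision threshold, reclassifies the surface
into four categories and evaluates discrimination (AUC), omission and
binomial significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raster import NODATA_INT, ClassMap, Raster

#: default class bounds: (medium lower, high lower); the lower edge of the
#: marginal class is the decision threshold.
DEFAULT_BOUNDS = (0.5, 0.75)
DEFAULT_THRESHOLD = 0.364
DEFAULT_THINNING_CELL_AREA_KM2 = 144.0


@dataclass
class EvaluationReport:
    auc: float
    omission_rate: float
    binomial_p: float
    threshold: float
    n_test: int = 0
    auc_sd: float | None = None

    def __post_init__(self) -> None:
        for name in ("auc", "omission_rate", "binomial_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def thin_records(
    records: pd.DataFrame,
    cell_area_km2: float = DEFAULT_THINNING_CELL_AREA_KM2,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Keep one record per square grid cell of area ``cell_area_km2``.

    The grid is anchored at the coordinate origin.  Within each occupied
    cell one record is retained uniformly at random.
    """
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    if len(records) == 0:
        return records.copy()
    rng = _rng(seed)
    side = float(np.sqrt(cell_area_km2))
    ix = np.floor(records["x_km"].to_numpy() / side).astype(int)
    iy = np.floor(records["y_km"].to_numpy() / side).astype(int)
    keep: list[int] = []
    cells = pd.DataFrame({"ix": ix, "iy": iy, "pos": np.arange(len(records))})
    for _, grp in cells.groupby(["ix", "iy"], sort=True):
        keep.append(int(grp["pos"].iloc[rng.integers(len(grp))]))
    keep.sort()
    return records.iloc[keep].reset_index(drop=True)


def split_train_test(
    records: pd.DataFrame,
    train_fraction: float = 0.7,
    n_replicates: int = 10,
    seed: int | np.random.Generator = 0,
    mode: str = "redraw",
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Random train/test partitions, re-drawn independently per replicate.

    ``mode="redraw"`` (default): each replicate is an independent random
    70/30-style partition of the records.  ``mode="bootstrap"``: the train
    side is sampled with replacement and the test side holds the out-of-bag
    records.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(records) < 2:
        raise ValueError("need at least 2 records to partition")
    if mode not in ("redraw", "bootstrap"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = _rng(seed)
    n = len(records)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    out = []
    for _ in range(n_replicates):
        if mode == "redraw":
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
        else:
            tr = rng.integers(n, size=n_train)
            te = np.setdiff1d(np.arange(n), tr)
        out.append(
            (records.iloc[np.sort(tr)].reset_index(drop=True),
             records.iloc[np.sort(te)].reset_index(drop=True))
        )
    return out


def auc_presence_background(presence_scores, background_scores) -> float:
    """Rank AUC: P(presence > background) + 0.5 P(tie)."""
    pres = np.asarray(presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("presence and background score lists must be non-empty")
    u = stats.mannwhitneyu(pres, back, alternative="two-sided").statistic
    return float(u) / (pres.size * back.size)


def candidate_thresholds(presence_scores, background_scores) -> np.ndarray:
    """Midpoints between adjacent distinct pooled scores, plus {0, 1}."""
    pooled = np.unique(np.concatenate([presence_scores, background_scores]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    return np.unique(np.concatenate([[0.0], mids, [1.0]]))


def select_threshold_max_ss(presence_scores, background_scores) -> float:
    """Threshold maximizing sensitivity + specificity (smallest maximizer).

    sensitivity = fraction of presences >= t; specificity = fraction of
    background < t.
    """
    pres = np.asarray(presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("presence and background score lists must be non-empty")
    cands = candidate_thresholds(pres, back)
    sens = (pres[None, :] >= cands[:, None]).mean(axis=1)
    spec = (back[None, :] < cands[:, None]).mean(axis=1)
    total = sens + spec
    # treat float near-ties as ties so the smallest maximizer wins
    best = np.flatnonzero(total >= total.max() - 1e-9)[0]
    return float(cands[int(best)])


def reclassify(
    raster: Raster,
    threshold: float = DEFAULT_THRESHOLD,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> ClassMap:
    """Four-class map: unsuitable [0,t), marginal [t,b1), medium [b1,b2), high [b2,1].

    The value exactly at the decision threshold is classed suitable
    (>= convention); the top class closes at 1.
    """
    b1, b2 = bounds
    if not threshold < b1 < b2:
        raise ValueError(f"need threshold < {b1} < {b2}")
    v = raster.values
    codes = np.digitize(v, [threshold, b1, b2], right=False)
    codes = np.where(np.isfinite(v), codes, NODATA_INT).astype(int)
    return ClassMap(
        codes, cell_km=raster.cell_km, origin=raster.origin, bounds=(threshold, b1, b2)
    )


def sample_background_scores(
    raster: Raster, n: int = 10_000, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Suitability values at ``n`` uniformly random non-NoData cells."""
    rng = _rng(seed)
    vals = raster.values[np.isfinite(raster.values)].ravel()
    if vals.size == 0:
        raise ValueError("raster has no data cells")
    return vals[rng.integers(vals.size, size=n)]


def evaluate(
    raster: Raster,
    test_records: pd.DataFrame,
    threshold: float,
    n_background: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> EvaluationReport:
    """Omission, binomial significance and AUC of a thresholded model.

    omission = fraction of test records on cells with value < threshold.
    binomial_p = one-sided P(X >= successes) for X ~ Binomial(n, q) with q
    the fraction of non-NoData area predicted suitable.
    """
    scores = raster.sample(test_records["x_km"].to_numpy(), test_records["y_km"].to_numpy())
    if np.isnan(scores).any():
        bad = np.flatnonzero(np.isnan(scores))
        raise ValueError(f"test records on NoData cells at indices {bad.tolist()}")
    n = scores.size
    hits = int((scores >= threshold).sum())
    omission = (n - hits) / n if n else 0.0
    finite = raster.values[np.isfinite(raster.values)]
    q = float((finite >= threshold).mean())
    binom_p = float(stats.binom.sf(hits - 1, n, q)) if n else 1.0
    back = sample_background_scores(raster, n_background, seed)
    auc = auc_presence_background(scores, back)
    return EvaluationReport(
        auc=auc, omission_rate=omission, binomial_p=min(binom_p, 1.0),
        threshold=threshold, n_test=n,
    )


def cross_validate(
    raster: Raster,
    records: pd.DataFrame,
    train_fraction: float = 0.7,
    n_replicates: int = 10,
    n_background: int = 10_000,
    seed: int | np.random.Generator = 0,
    mode: str = "redraw",
) -> dict:
    """Replicate-level threshold selection and evaluation.

    Per replicate, the max sensitivity+specificity threshold is chosen on
    the test scores against a shared background sample; the reported
    threshold is the replicate mean.
    """
    rng = _rng(seed)
    back = sample_background_scores(raster, n_background, rng)
    splits = split_train_test(records, train_fraction, n_replicates, rng, mode=mode)
    aucs, thresholds, omissions = [], [], []
    for _, test in splits:
        scores = raster.sample(test["x_km"].to_numpy(), test["y_km"].to_numpy())
        scores = scores[np.isfinite(scores)]
        t = select_threshold_max_ss(scores, back)
        aucs.append(auc_presence_background(scores, back))
        thresholds.append(t)
        omissions.append(float((scores < t).mean()))
    threshold = float(np.mean(thresholds))
    report = evaluate(raster, records, threshold, n_background, rng)
    return {
        "auc": float(np.mean(aucs)),
        "auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        "threshold": threshold,
        "omission_rate": float(np.mean(omissions)),
        "binomial_p": report.binomial_p,
        "n_replicates": n_replicates,
    }
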