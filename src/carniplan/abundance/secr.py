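"""Bayesian spatially explicit capture-recapture with data augmentation.

Model
-----
The unknown population is embedded in a super-population of M individuals
with inclusion indicators z_i ~ Bernoulli(psi).  Activity centers s_i are
uniform over a discretized state space.  Detection of individual i at trap
j on each occasion is Bernoulli with p_ij = p0 * exp(-d_ij^2 / (2 sigma^2)).
Priors are flat: p0, psi ~ U(0,1), sigma ~ U(0, sigma_max).  Inference is
Metropolis-within-Gibbs: discrete Gibbs updates for centers and inclusion
indicators, a Beta draw for psi, random-walk Metropolis for p0 and sigma.
NSuper = sum(z) per retained sample; density = NSuper / state-space area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..capture import CaptureData
from ..raster import ClassMap


class InsufficientDataError(ValueError):
    """Capture data below the usability bar for SECR fitting."""


@dataclass
class SecrConfig:
    state_space_buffer_km: float = 15.0
    state_space_cell_km: float = 1.0
    M: int | None = None  # default: 4 x observed individuals, min 50
    n_iter: int = 52_000
    n_burn: int = 2_000
    thin: int = 10
    seed: int = 0
    min_individuals: int = 6
    sigma_max_km: float | None = None  # default: half the state-space diagonal
    fixed_psi: float | None = None

    def __post_init__(self) -> None:
        if self.state_space_buffer_km <= 0:
            raise ValueError("state_space_buffer_km must be positive")
        if self.state_space_cell_km <= 0:
            raise ValueError("state_space_cell_km must be positive")
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be < n_iter")


@dataclass
class SecrFit:
    samples: pd.DataFrame  # columns: p0, sigma, psi, nsuper, density
    summary: dict[str, dict[str, float]]
    area_km2: float
    M: int
    n_detected: int
    geweke: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    @property
    def density_mean(self) -> float:
        return self.summary["density"]["mean"]

    @property
    def density_ci95(self) -> tuple[float, float]:
        s = self.summary["density"]
        return (s["ci_lower"], s["ci_upper"])

    def nsuper_estimate(self) -> tuple[int, int, int]:
        """(point, low, high) population numbers from the NSuper posterior."""
        ns = self.samples["nsuper"].to_numpy()
        lo, hi = np.percentile(ns, [2.5, 97.5])
        return (int(round(float(ns.mean()))), int(np.floor(lo)), int(np.ceil(hi)))


def build_state_space(
    traps: pd.DataFrame,
    buffer_km: float,
    cell_km: float,
    habitat_mask: ClassMap | None = None,
) -> tuple[np.ndarray, float]:
    """Discretized state space: (G, 2) cell-centre coordinates and area km^2.

    A square grid over the trap bounding box expanded by ``buffer_km``.
    With a habitat mask, only cells whose centre falls on suitable habitat
    are retained (centres outside the mask extent are kept: unknown is not
    unsuitable).
    """
    xy = traps[["x_km", "y_km"]].to_numpy(dtype=float)
    xmin, ymin = xy.min(axis=0) - buffer_km
    xmax, ymax = xy.max(axis=0) + buffer_km
    nx = max(int(np.ceil((xmax - xmin) / cell_km)), 1)
    ny = max(int(np.ceil((ymax - ymin) / cell_km)), 1)
    xs = xmin + (np.arange(nx) + 0.5) * cell_km
    ys = ymin + (np.arange(ny) + 0.5) * cell_km
    gx, gy = np.meshgrid(xs, ys)
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    if habitat_mask is not None:
        r = habitat_mask.as_raster()
        inside = r.contains(cells[:, 0], cells[:, 1])
        keep = np.ones(len(cells), dtype=bool)
        if inside.any():
            vals = r.sample(cells[inside, 0], cells[inside, 1])
            keep[inside] = vals >= 1
        cells = cells[keep]
        if len(cells) == 0:
            raise ValueError("habitat mask leaves no state-space cells")
    return cells, float(len(cells) * cell_km**2)


def _pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)


def marginal_loglik(
    y_counts: np.ndarray,
    n_occasions: int,
    trap_xy: np.ndarray,
    cell_xy: np.ndarray,
    p0: float,
    sigma: float,
    psi: float,
    M: int,
) -> float:
    """Exact marginal log-likelihood of the observed histories.

    Individuals are independent given parameters, so the latent (z, center)
    pair marginalizes per individual:

        L_i   = psi * (1/G) * sum_c prod_j p_cj^y_ij (1-p_cj)^(K-y_ij)
        L_aug = psi * (1/G) * sum_c prod_j (1-p_cj)^K + (1 - psi)

    where the observed history probability is that of the specific binary
    occasion-by-trap array (occasions are iid, so only the per-trap counts
    y_ij matter).
    """
    y = np.asarray(y_counts, dtype=float)
    n, J = y.shape
    if n > M:
        raise ValueError("M must be at least the number of detected individuals")
    d2 = _pairwise_sq_dists(np.asarray(cell_xy, float), np.asarray(trap_xy, float))
    G = d2.shape[0]
    p = p0 * np.exp(-d2 / (2.0 * sigma**2))  # G x J
    with np.errstate(divide="ignore"):
        logp = np.log(p)
        log1m = np.log1p(-p)
    base = n_occasions * log1m.sum(axis=1)  # G: log P(all-zero history | c)
    ll = 0.0
    from scipy.special import logsumexp

    for i in range(n):
        percell = base + y[i] @ (logp - log1m).T
        ll += np.log(psi) + logsumexp(percell) - np.log(G)
    l0 = np.logaddexp(np.log(psi) + logsumexp(base) - np.log(G), np.log1p(-psi))
    ll += (M - n) * l0
    return float(ll)


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    n = x.size
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2):]
    denom = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def fit_secr(
    data: CaptureData,
    config: SecrConfig | None = None,
    habitat_mask: ClassMap | None = None,
) -> SecrFit:
    """Fit the data-augmented SECR model by MCMC.

    Cubs and unknown-age individuals are excluded before fitting.  Requires
    at least ``config.min_individuals`` detected adults and at least one
    spatial recapture (an individual seen at two or more traps).
    """
    config = config or SecrConfig()
    adults = data.subset_adults()
    n = adults.n_individuals
    if n == 0:
        raise InsufficientDataError("no detected adult individuals")
    if n < config.min_individuals:
        raise InsufficientDataError(
            f"{n} adult individuals recorded; fewer than the usability bar "
            f"({config.min_individuals})"
        )
    if not adults.has_spatial_recapture():
        raise InsufficientDataError(
            "no spatial recaptures (no individual detected at >= 2 traps); "
            "use the non-spatial jackknife + buffer path instead"
        )

    rng = np.random.default_rng(config.seed)
    K = adults.n_occasions
    traps = adults.trap_coords()
    cells, area_km2 = build_state_space(
        adults.traps, config.state_space_buffer_km, config.state_space_cell_km, habitat_mask
    )
    G = len(cells)
    M = config.M if config.M is not None else max(4 * n, 50)
    if M <= n:
        raise ValueError("M must exceed the number of detected individuals")
    diag = np.sqrt(
        (cells[:, 0].max() - cells[:, 0].min()) ** 2
        + (cells[:, 1].max() - cells[:, 1].min()) ** 2
    )
    sigma_max = config.sigma_max_km if config.sigma_max_km is not None else diag / 2.0

    D2 = _pairwise_sq_dists(cells, traps)  # G x J
    Y = np.zeros((M, traps.shape[0]))
    Y[:n] = adults.detections.sum(axis=2)

    # --- initial state
    p0 = 0.1
    sigma = min(max(np.sqrt(D2.min(axis=0).mean()), 0.5), sigma_max * 0.5)
    psi = min(2.0 * n / M, 0.9) if config.fixed_psi is None else config.fixed_psi
    z = np.zeros(M, dtype=bool)
    z[:n] = True
    z[n:] = rng.random(M - n) < psi
    s = rng.integers(G, size=M)
    for i in range(n):  # start detected individuals near their detections
        w = Y[i] / Y[i].sum()
        cen = w @ traps
        s[i] = int(np.argmin(((cells - cen) ** 2).sum(axis=1)))

    detected = np.zeros(M, dtype=bool)
    detected[:n] = True

    def subset_loglik(p0_v: float, sigma_v: float, cell_idx: np.ndarray, Yact: np.ndarray) -> float:
        p = p0_v * np.exp(-D2[cell_idx] / (2.0 * sigma_v**2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = Yact * np.log(p) + (K - Yact) * np.log1p(-p)
        ll = np.where((Yact == 0) & (p == 0), 0.0, ll)
        return float(np.nansum(ll)) if np.isfinite(ll).all() else -np.inf

    p0_step, sigma_step = 0.05, 0.25 * sigma
    acc = np.zeros(2)
    tries = np.zeros(2)
    kept = {k: [] for k in ("p0", "sigma", "psi", "nsuper", "density")}
    warn_list: list[str] = []

    Ydet = Y[:n]
    for it in range(config.n_iter):
        p = p0 * np.exp(-D2 / (2.0 * sigma**2))
        with np.errstate(divide="ignore"):
            logp = np.log(p)
            log1m = np.log1p(-p)
        base = K * log1m.sum(axis=1)  # G: log P(all-zero history | center)
        # p underflows to 0 at far cells; -inf log-odds would turn the
        # zero-count matmul terms into NaN, so clamp to a huge finite penalty
        logodds = np.maximum(logp - log1m, -1e12)

        # centers: Gibbs over cells.  Detected individuals have individual
        # likelihood rows; included-but-undetected ones share the all-zero
        # likelihood (base), and excluded ones follow the uniform prior.
        LLdet = Ydet @ logodds.T + base  # n x G
        s[:n] = np.argmax(LLdet + rng.gumbel(size=(n, G)), axis=1)
        aug_on = np.flatnonzero(z[n:]) + n
        if aug_on.size:
            w = np.exp(base - base.max())
            s[aug_on] = rng.choice(G, size=aug_on.size, p=w / w.sum())
        aug_off = np.flatnonzero(~z[n:]) + n
        s[aug_off] = rng.integers(G, size=aug_off.size)

        # inclusion indicators for undetected individuals
        ll_zero = base[s]  # log P(no detections | center)
        with np.errstate(over="ignore"):
            logit = np.log(psi) - np.log1p(-psi) + ll_zero
            pz = 1.0 / (1.0 + np.exp(-logit))
        z = detected | (rng.random(M) < pz)

        nz = int(z.sum())
        if config.fixed_psi is None:
            psi = rng.beta(1 + nz, 1 + M - nz)

        # Metropolis for p0 and sigma given (z, s)
        act = np.flatnonzero(z)
        cell_idx = s[act]
        Yact = Y[act]
        ll_cur = subset_loglik(p0, sigma, cell_idx, Yact)
        prop = p0 + rng.normal(0.0, p0_step)
        tries[0] += 1
        if 0.0 < prop < 1.0:
            ll_new = subset_loglik(prop, sigma, cell_idx, Yact)
            if np.log(rng.random()) < ll_new - ll_cur:
                p0, ll_cur = prop, ll_new
                acc[0] += 1
        prop = sigma + rng.normal(0.0, sigma_step)
        tries[1] += 1
        if 0.0 < prop < sigma_max:
            ll_new = subset_loglik(p0, prop, cell_idx, Yact)
            if np.log(rng.random()) < ll_new - ll_cur:
                sigma = prop
                acc[1] += 1

        if it < config.n_burn and it and it % 200 == 0:  # adapt during burn-in
            for w_i, step_name in ((0, "p0"), (1, "sigma")):
                rate = acc[w_i] / max(tries[w_i], 1)
                scale = np.exp(np.clip(rate - 0.4, -0.5, 0.5))
                if step_name == "p0":
                    p0_step = float(np.clip(p0_step * scale, 1e-4, 0.5))
                else:
                    sigma_step = float(np.clip(sigma_step * scale, 1e-3, sigma_max))
            acc[:] = 0
            tries[:] = 0

        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
            kept["p0"].append(p0)
            kept["sigma"].append(sigma)
            kept["psi"].append(psi)
            kept["nsuper"].append(nz)
            kept["density"].append(100.0 * nz / area_km2)

    samples = pd.DataFrame(kept)
    if (samples["nsuper"] >= M).mean() > 0.01:
        msg = f"posterior mass at NSuper = M ({M}); refit with a larger M"
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        warn_list.append(msg)

    summary: dict[str, dict[str, float]] = {}
    geweke: dict[str, float] = {}
    for col in samples.columns:
        x = samples[col].to_numpy(dtype=float)
        lo, hi = np.percentile(x, [2.5, 97.5])
        summary[col] = {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "ci_lower": float(lo),
            "ci_upper": float(hi),
        }
        geweke[col] = _geweke_z(x)
    return SecrFit(
        samples=samples,
        summary=summary,
        area_km2=area_km2,
        M=M,
        n_detected=n,
        geweke=geweke,
        warnings=warn_list,
    )
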