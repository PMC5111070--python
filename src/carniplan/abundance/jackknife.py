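"""Burnham-Overton jackknife abundance estimation under model Mh.

Input is the capture-frequency vector f, where f_i is the number of
distinct individuals captured on exactly i of the t occasions.  Estimators
of orders 1-5 use the standard published coefficients; the order is chosen
by the sequential chi-square test on successive differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MAX_ORDER = 5


@dataclass
class JackknifeResult:
    n_hat: float
    se: float
    order: int
    estimates: dict[int, float]
    p_values: dict[int, float]
    interpolated: bool = False


def jackknife_coefficients(t: int, order: int) -> np.ndarray:
    """Coefficients a_{ik}, i = 1..t, with N_hat_k = sum_i a_{ik} f_i.

    For i > k the coefficient is 1.  Orders 1-5 follow the standard
    Burnham-Overton table.
    """
    if t < 2:
        raise ValueError("need at least 2 occasions")
    if not 1 <= order <= MAX_ORDER:
        raise ValueError(f"order must be in 1..{MAX_ORDER}")
    if order > t - 1:
        raise ValueError(f"order {order} requires at least {order + 1} occasions")
    a = np.ones(t, dtype=float)
    T = float(t)
    if order == 1:
        a[0] = 1 + (T - 1) / T
    elif order == 2:
        a[0] = 1 + (2 * T - 3) / T
        a[1] = 1 - (T - 2) ** 2 / (T * (T - 1))
    elif order == 3:
        a[0] = 1 + (3 * T - 6) / T
        a[1] = 1 - (3 * T**2 - 15 * T + 19) / (T * (T - 1))
        a[2] = 1 + (T - 3) ** 3 / (T * (T - 1) * (T - 2))
    elif order == 4:
        a[0] = 1 + (4 * T - 10) / T
        a[1] = 1 - (6 * T**2 - 36 * T + 55) / (T * (T - 1))
        a[2] = 1 + (4 * T**3 - 42 * T**2 + 148 * T - 175) / (T * (T - 1) * (T - 2))
        a[3] = 1 - (T - 4) ** 4 / (T * (T - 1) * (T - 2) * (T - 3))
    else:
        a[0] = 1 + (5 * T - 15) / T
        a[1] = 1 - (10 * T**2 - 70 * T + 125) / (T * (T - 1))
        a[2] = 1 + (10 * T**3 - 120 * T**2 + 485 * T - 660) / (T * (T - 1) * (T - 2))
        a[3] = 1 - ((T - 4) ** 5 - (T - 5) ** 5) / (T * (T - 1) * (T - 2) * (T - 3))
        a[4] = 1 + (T - 5) ** 5 / (T * (T - 1) * (T - 2) * (T - 3) * (T - 4))
    return a


def _estimate(f: np.ndarray, t: int, order: int) -> tuple[float, float]:
    a = jackknife_coefficients(t, order)
    n_hat = float(a @ f)
    var = float((a**2) @ f) - n_hat
    return n_hat, float(np.sqrt(max(var, 0.0)))


def jackknife_mh(
    capture_frequencies,
    n_occasions: int,
    alpha: float = 0.05,
    interpolate: bool = True,
) -> JackknifeResult:
    """Jackknife Mh abundance with sequential order selection.

    The test of order k compares N_hat_{k+1} with N_hat_k via the
    chi-square statistic of their difference; the selected order is the
    first k whose test is non-significant at ``alpha``.  With
    ``interpolate=True`` and selected order m >= 2, the point estimate is a
    p-value-weighted blend of N_hat_{m-1} and N_hat_m, smoothing the
    discontinuity of hard selection.
    """
    f = np.zeros(n_occasions, dtype=float)
    fin = np.asarray(capture_frequencies, dtype=float)
    if n_occasions < 2:
        raise ValueError("need at least 2 occasions")
    if fin.size > n_occasions:
        raise ValueError("frequency vector longer than n_occasions")
    f[: fin.size] = fin
    if f.sum() < 1:
        raise ValueError("no captured individuals")
    s = float(f.sum())

    max_k = min(MAX_ORDER, n_occasions - 1)
    estimates: dict[int, float] = {}
    ses: dict[int, float] = {}
    for k in range(1, max_k + 1):
        estimates[k], ses[k] = _estimate(f, n_occasions, k)

    p_values: dict[int, float] = {}
    selected = max_k
    for k in range(1, max_k):
        a_k = jackknife_coefficients(n_occasions, k)
        a_k1 = jackknife_coefficients(n_occasions, k + 1)
        b = a_k1 - a_k
        diff = estimates[k + 1] - estimates[k]
        if s > 1:
            var = (s / (s - 1.0)) * float((b**2) @ f - diff**2 / s)
        else:
            var = 0.0
        if var <= 0:
            p = 1.0
        else:
            p = float(stats.chi2.sf(diff**2 / var, df=1))
        p_values[k] = p
        if p > alpha:
            selected = k
            break

    n_hat, se = estimates[selected], ses[selected]
    interpolated = False
    if interpolate and selected >= 2:
        p_prev = p_values.get(selected - 1, 0.0)
        c = max(0.0, min(1.0, 1.0 - p_prev / alpha))
        n_hat = c * estimates[selected] + (1.0 - c) * estimates[selected - 1]
        se = c * ses[selected] + (1.0 - c) * ses[selected - 1]
        interpolated = True
    n_hat = max(n_hat, s)  # abundance cannot be below the observed count
    return JackknifeResult(
        n_hat=n_hat,
        se=se,
        order=selected,
        estimates=estimates,
        p_values=p_values,
        interpolated=interpolated,
    )
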