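"""Classical and sequential Mann-Kendall trend statistics.

The Mann-Kendall (MK) test is a rank-based nonparametric test for a
monotone trend in a time series; it requires neither normality nor
linearity. Its sequential form produces the forward (UF) and backward (UB)
standardized curves whose intersection inside the confidence band marks a
trend-change ("mutation") point. This module also implements the backward
suffix scan that locates the endogenous-respiration onset t2 on an OUR
curve: the terminal portion without an obvious change trend is the
endogenous plateau.

Conventions
-----------
* The classical statistic ``S`` uses the three-valued sign (ties count 0);
  ``Var(S) = n(n-1)(2n+5)/18`` with no tie correction (ties are rare in OUR
  data; documented limitation).
* The sequential rank count ``r_i`` is the number of earlier values
  strictly below ``x_i``; ``E[S_k] = k(k-1)/4``;
  ``var[S_k] = k(k-1)(2k+5)/72``; ``UF_1`` is defined as 0 since
  ``var[S_1] = 0``.
* Critical values: two-sided standard-normal quantiles by default
  (1.96 at alpha = 0.05, 2.576 at alpha = 0.01). The one-sided set
  1.28 / 1.64 / 2.32 at 90/95/99% confidence, applied to |Z|, is exposed
  as the named set ``"paper_onesided"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import OURSeries

__all__ = [
    "TrendTestResult",
    "SequentialMKResult",
    "mk_trend_test",
    "sequential_mk",
    "detect_endogenous_onset",
    "detect_mutation_point",
    "critical_value",
    "PAPER_ONESIDED_CRITICALS",
    "round_half_up",
]

#: |Z| thresholds at 90/95/99% confidence as printed in older applied-MK
#: practice (one-sided normal quantiles applied to |Z|).
PAPER_ONESIDED_CRITICALS = {0.10: 1.28, 0.05: 1.64, 0.01: 2.32}


def critical_value(alpha: float, critical_set: str = "two-sided") -> float:
    """Critical |Z| for significance level ``alpha``.

    ``critical_set="two-sided"`` gives the standard two-sided normal
    quantile; ``"paper_onesided"`` gives the 1.28/1.64/2.32 set (exact
    values required; other alphas fall back to the one-sided quantile).
    """
    if critical_set == "two-sided":
        return float(stats.norm.ppf(1.0 - alpha / 2.0))
    if critical_set == "paper_onesided":
        if alpha in PAPER_ONESIDED_CRITICALS:
            return PAPER_ONESIDED_CRITICALS[alpha]
        return float(stats.norm.ppf(1.0 - alpha))
    raise ValueError(f"unknown critical set {critical_set!r}")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table display)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _values(series) -> np.ndarray:
    if isinstance(series, OURSeries):
        return np.asarray(series.our, dtype=float)
    return np.asarray(series, dtype=float)


def _times(series, n: int) -> np.ndarray:
    if isinstance(series, OURSeries):
        return np.asarray(series.times, dtype=float)
    return np.arange(n, dtype=float)


@dataclass(frozen=True)
class TrendTestResult:
    """Classical MK test output: S, Var(S), continuity-corrected Z."""

    n: int
    s_stat: int
    var_s: float
    z_mk: float
    alpha: float
    significant: bool
    direction: str  # "up" | "down" | "none"


@dataclass(frozen=True)
class SequentialMKResult:
    """Sequential MK output aligned to forward time.

    ``uf`` is the standardized forward statistic; ``ub`` is obtained by
    applying the same recipe to the reversed series, negating, and
    re-reversing onto forward indices.
    """

    k: np.ndarray
    times: np.ndarray
    values: np.ndarray
    r: np.ndarray
    s_k: np.ndarray
    e_sk: np.ndarray
    var_sk: np.ndarray
    uf: np.ndarray
    ub: np.ndarray


def mk_trend_test(series, alpha: float = 0.01,
                  critical_set: str = "two-sided") -> TrendTestResult:
    """Classical Mann-Kendall trend test.

    ``S`` is the sum of sign(x_j - x_i) over all pairs i < j;
    ``Z`` carries the +/-1 continuity correction and is 0 when S = 0.
    """
    x = _values(series)
    n = len(x)
    if n < 2:
        raise ValueError("Mann-Kendall test needs at least 2 values")
    diff = x[None, :] - x[:, None]
    s = int(np.sign(diff[np.triu_indices(n, k=1)]).sum())
    var_s = n * (n - 1) * (2 * n + 5) / 18.0
    if s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    crit = critical_value(alpha, critical_set)
    significant = abs(z) >= crit
    direction = "none"
    if significant:
        direction = "up" if s > 0 else "down"
    return TrendTestResult(n=n, s_stat=s, var_s=var_s, z_mk=z,
                           alpha=alpha, significant=significant,
                           direction=direction)


def _sequential_uf(x: np.ndarray) -> tuple[np.ndarray, ...]:
    """r_i, S_k, E[S_k], var[S_k], UF_k for one direction."""
    n = len(x)
    r = np.array([int(np.sum(x[:i] < x[i])) for i in range(n)])
    s_k = np.cumsum(r).astype(float)
    k = np.arange(1, n + 1, dtype=float)
    e_sk = k * (k - 1) / 4.0
    var_sk = k * (k - 1) * (2 * k + 5) / 72.0
    uf = np.zeros(n)
    nz = var_sk > 0
    uf[nz] = (s_k[nz] - e_sk[nz]) / np.sqrt(var_sk[nz])
    return r, s_k, e_sk, var_sk, uf


def sequential_mk(series) -> SequentialMKResult:
    """Sequential Mann-Kendall statistics (forward UF and backward UB)."""
    x = _values(series)
    n = len(x)
    if n < 3:
        raise ValueError("sequential Mann-Kendall needs at least 3 values")
    t = _times(series, n)
    r, s_k, e_sk, var_sk, uf = _sequential_uf(x)
    _, _, _, _, uf_rev = _sequential_uf(x[::-1])
    ub = -uf_rev[::-1]
    return SequentialMKResult(k=np.arange(1, n + 1), times=t, values=x,
                              r=r, s_k=s_k, e_sk=e_sk, var_sk=var_sk,
                              uf=uf, ub=ub)


def _level_band(window: np.ndarray, alpha: float, level_tol: float) -> float:
    """Half-width of the plateau acceptance band around the window mean.

    The band is the wider of a relative floor (``level_tol`` times the
    plateau level — the "no obvious change" criterion at low noise) and a
    two-sided t prediction interval for one new observation, which adapts
    the band to the sensor noise actually present in the plateau.
    """
    m = len(window)
    mean = float(window.mean())
    s = float(window.std(ddof=1))
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, m - 1))
    return max(level_tol * abs(mean), t_crit * s * math.sqrt(1.0 + 1.0 / m))


def detect_endogenous_onset(series: OURSeries, alpha: float = 0.05,
                            min_window: int = 3, level_tol: float = 0.05,
                            critical_set: str = "paper_onesided"):
    """Locate the endogenous-respiration onset t2 by a backward suffix scan.

    Starting from the last ``min_window`` points, the scan prepends one
    earlier point at a time. A grown suffix is accepted while (a) the
    classical MK test on the suffix shows no significant trend at ``alpha``
    and (b) the candidate point stays inside the plateau acceptance band
    (the wider of ``level_tol`` relative to the plateau mean and a t
    prediction interval at ``alpha``) — the quantitative reading of
    "no obvious change trend": the plateau must be trend-free and level.
    t2 is the time of the earliest accepted point.

    Returns ``(t2, (i_start, i_end), trace)`` where the index range is the
    plateau window (inclusive) and ``trace`` lists the per-suffix
    :class:`TrendTestResult` objects for audit.

    Raises
    ------
    ValueError
        If the scan terminates on a stretch that is not level — the curve
        never settles ("no endogenous plateau detected").
    """
    x = np.asarray(series.our, dtype=float)
    t = np.asarray(series.times, dtype=float)
    n = len(x)
    if n < min_window + 1:
        raise ValueError(
            f"series too short: need at least {min_window + 1} points"
        )

    def rejects(cand_value: float, window: np.ndarray) -> bool:
        """Level-gate and trend-gate decision for one candidate point."""
        if abs(cand_value - float(window.mean())) > _level_band(
                window, alpha, level_tol):
            return True
        res = mk_trend_test(np.concatenate([[cand_value], window]),
                            alpha=alpha, critical_set=critical_set)
        trace.append(res)
        return res.significant

    # the terminal seed window scales with series length so that the
    # acceptance band is estimated from a stable number of points on
    # densely sampled records; short tables start from min_window points
    start = n - max(min_window, n // 10)
    trace = [mk_trend_test(x[start:], alpha=alpha, critical_set=critical_set)]
    while start > 0:
        window = x[start:]
        if rejects(x[start - 1], window):
            # a single aberrant point must not end the plateau: the stop
            # stands only if the next-earlier point also fails against the
            # same (uncontaminated) window; otherwise the spike is absorbed
            if start - 2 < 0 or rejects(x[start - 2], window):
                break
            start -= 2
            continue
        start -= 1

    # validate that what the scan kept is actually level: its range must be
    # explainable by the relative floor or by the point-to-point scatter
    # (an MK test alone cannot flag a monotone run of < 4 points, and is
    # magnitude-blind for longer ones)
    w = x[start:]
    m = len(w)
    sd_diff = float(np.std(np.diff(w), ddof=1)) / math.sqrt(2.0)
    bound = max(3.0 * level_tol * abs(float(w.mean())),
                2.8 * sd_diff * math.sqrt(2.0 * math.log(max(m, 3))))
    if np.ptp(w) > bound:
        raise ValueError("no endogenous plateau detected")
    return float(t[start]), (start, n - 1), trace


def detect_mutation_point(seq: SequentialMKResult, alpha: float = 0.05,
                          critical_set: str = "two-sided"):
    """Locate the UF/UB intersection (trend mutation point).

    Finds sign changes of ``uf - ub`` between consecutive indices and
    linearly interpolates the crossing time. Returns
    ``(t_cross, crossing_within_band, degenerate)``; ``t_cross`` is None
    when the curves never cross. ``crossing_within_band`` is True when
    |UF| at the crossing is inside the two-sided confidence band. When
    ``uf`` and ``ub`` coincide everywhere the first time point is returned
    with ``degenerate=True``.
    """
    d = seq.uf - seq.ub
    t = seq.times
    crit = critical_value(alpha, critical_set)
    if np.allclose(d, 0.0):
        return float(t[0]), bool(abs(seq.uf[0]) <= crit), True
    for i in range(len(d) - 1):
        a, b = d[i], d[i + 1]
        if a == 0.0:
            uf_c = seq.uf[i]
            return float(t[i]), bool(abs(uf_c) <= crit), False
        if a * b < 0:
            frac = a / (a - b)
            t_cross = t[i] + frac * (t[i + 1] - t[i])
            uf_c = seq.uf[i] + frac * (seq.uf[i + 1] - seq.uf[i])
            return float(t_cross), bool(abs(uf_c) <= crit), False
    if d[-1] == 0.0:
        return float(t[-1]), bool(abs(seq.uf[-1]) <= crit), False
    return None, False, False
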