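"""Oxygen-uptake-rate extraction from sealed-cycle DO traces.

Within each sealed measurement cycle of the batch respirometer the DO
concentration declines (to a good approximation linearly over a few
minutes) at the volumetric oxygen uptake rate. The OUR point for a cycle
is the negative of the ordinary-least-squares slope of DO on elapsed time,
converted from mg O2/(L*s) to mg O2/(L*h). Cycles whose DO-time relation
is not convincingly linear (r^2 below a gate, default 0.95) are rejected
and reported, mirroring the practice of keeping only the linear portion of
each DO-t curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DOTrace, OURSeries

__all__ = ["SlopeFit", "fit_cycle_slope", "extract_our", "RejectedCycle"]


@dataclass(frozen=True)
class SlopeFit:
    """OLS line through one cycle's DO samples.

    slope is in mg O2/(L*s) (negative while oxygen is consumed);
    r_squared is the squared Pearson correlation, defined as 0 for a
    constant-DO cycle.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class RejectedCycle:
    start_time_min: float
    fit: SlopeFit
    reason: str


def fit_cycle_slope(samples) -> SlopeFit:
    """OLS fit of DO on elapsed seconds for one cycle.

    ``samples`` is a sequence of (elapsed_s, do_conc) pairs or any object
    with ``elapsed_s`` and ``do_conc`` arrays.
    """
    if hasattr(samples, "elapsed_s"):
        t = np.asarray(samples.elapsed_s, dtype=float)
        y = np.asarray(samples.do_conc, dtype=float)
    else:
        arr = np.asarray(list(samples), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("samples must be (elapsed_s, do_conc) pairs")
        t, y = arr[:, 0], arr[:, 1]
    if len(t) < 3:
        raise ValueError("slope fitting needs at least 3 samples")
    if np.ptp(t) == 0:
        raise ValueError("all sample times identical")
    if len(np.unique(t)) != len(t):
        raise ValueError("sample times must be distinct")
    if np.ptp(y) == 0:
        # constant DO: zero slope, r^2 defined as 0 (rejected by the gate)
        return SlopeFit(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                        n_points=len(t))
    res = stats.linregress(t, y)
    return SlopeFit(slope=float(res.slope), intercept=float(res.intercept),
                    r_squared=float(res.rvalue ** 2), n_points=len(t))


def extract_our(trace: DOTrace, min_r2: float = 0.95,
                trim: tuple[float, float] = (10.0, 0.0),
                label: str = "extracted"):
    """Convert a DO trace into an OUR series.

    One OUR point per accepted cycle, assigned to the cycle start time:
    OUR = -slope * 3600, floored at 0. The first ``trim[0]`` and last
    ``trim[1]`` seconds of every cycle are discarded (probe settling).
    Cycles with r^2 below ``min_r2`` are dropped and returned in the
    rejection log.

    Returns ``(series, rejections)``.
    """
    skip_start, skip_end = trim
    times, ours = [], []
    rejections: list[RejectedCycle] = []
    for cyc in trace.cycles:
        t = cyc.elapsed_s
        keep = (t >= t[0] + skip_start) & (t <= t[-1] - skip_end)
        if keep.sum() < 3:
            keep = np.ones_like(t, dtype=bool)  # trim would starve the fit
        fit = fit_cycle_slope(
            np.column_stack([t[keep], cyc.do_conc[keep]])
        )
        if fit.r_squared < min_r2:
            rejections.append(RejectedCycle(cyc.start_time_min, fit,
                                            f"r^2 {fit.r_squared:.3f} < {min_r2}"))
            continue
        times.append(cyc.start_time_min)
        ours.append(max(-fit.slope * 3600.0, 0.0))
    if not times:
        raise ValueError("no usable cycles (all rejected by the r^2 gate)")
    if len(times) < 3:
        raise ValueError(
            f"only {len(times)} usable cycles; an OUR series needs >= 3"
        )
    return OURSeries(np.array(times), np.array(ours), label=label), rejections
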