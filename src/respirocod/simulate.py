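"""Synthetic batch-respirogram generator with known ground truth.

The simulator integrates a minimal two-substrate activated-sludge batch
model: readily biodegradable substrate Ss is taken up with Monod kinetics,
slowly biodegradable substrate Xs is hydrolysed to Ss with the saturating
surface law, and the biomass respires endogenously at a constant rate
(X_H held constant over the short batch).

    uptake    = (mu_max / Y_H) * Ss/(K_s + Ss) * X_H          [mg COD/(L d)]
    hydrolysis = k_h * X_H * (Xs/X_H)/(Xs/X_H + k_x)
                 * k_i/(k_i + Ss)                             [mg COD/(L d)]
    dSs/dt = -uptake + hydrolysis
    dXs/dt = -hydrolysis
    OUR_ex = (1 - Y_H) * uptake / 24                          [mg O2/(L h)]
    OUR_en = 1.42 * b_H * X_H / 24                            [mg O2/(L h)]

The ``k_i/(k_i + Ss)`` factor is a preferential-uptake switch: hydrolysis
turnover is repressed while readily biodegradable substrate is abundant,
which is what produces the cleanly staged respirogram the segmentation
method presumes (set ``k_i`` large to disable it). Without the switch the
hydrolysis oxygen consumed during the RBCOD limb is booked into the RBCOD
integral and no integration boundary can recover both pools.

Ground truth carried with every run: the noiseless OUR decomposition, the
stage boundaries t1* (Ss-driven OUR falls below 5% of hydrolysis-driven
OUR) and t2* (total exogenous OUR falls below 2% of endogenous), and
rbcod* = ss0, sbcod* = xs0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .core import Cycle, DOTrace, OURSeries

__all__ = [
    "SimulationConfig",
    "RespirogramTruth",
    "SimulatedRespirogram",
    "simulate_respirogram",
    "emit_do_trace",
    "scenario_s0x0",
]

COD_TO_VSS = 1.42


@dataclass(frozen=True)
class SimulationConfig:
    """Batch-respirometry scenario.

    Defaults emulate a domestic-wastewater batch on 2000 mg/L MLVSS
    sludge: ~190 mg COD/L biodegradable substrate split 40 (readily) /
    150 (slowly), endogenous plateau ~ 11.5 mg O2/(L h), RBCOD limb over
    the first ~15 min and hydrolysis-limited decay reaching the plateau
    well inside the run. Rate constants are effective values conditional
    on x_h being the whole COD-based biomass.
    """

    ss0: float = 40.0            # mg COD/L readily biodegradable
    xs0: float = 150.0           # mg COD/L slowly biodegradable
    x_h: float = 2840.0          # mg COD/L heterotrophs (2000 MLVSS * 1.42)
    y_h: float = 0.68            # g/g yield
    mu_max: float = 1.0          # 1/d effective max specific growth rate
    k_s: float = 1.0             # mg COD/L Monod half-saturation
    k_h: float = 0.5             # 1/d max specific hydrolysis rate
    k_x: float = 0.008           # g COD_Xs/g COD_XH switching constant
    k_i: float = 0.5             # mg COD/L hydrolysis repression constant
    b_h: float = 0.0684          # 1/d endogenous decay
    duration_min: float = 440.0
    sample_interval_min: float = 2.0
    noise_sd_frac: float = 0.02  # fraction of noiseless peak OUR
    seed: int = 20210112
    do_cycle: tuple[float, float, float] = (4.0, 10.0, 8.0)
    # (cycle_min, sample_s, do_start mg/L)

    def __post_init__(self):
        for name in ("x_h", "mu_max", "k_s", "k_h", "k_x", "k_i", "b_h",
                     "duration_min", "sample_interval_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.ss0 < 0 or self.xs0 < 0:
            raise ValueError("initial substrates must be non-negative")
        if not (0 < self.y_h < 1):
            raise ValueError("y_h must lie in (0, 1)")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be non-negative")


@dataclass(frozen=True)
class RespirogramTruth:
    """Noiseless decomposition and ground-truth quantities of one run."""

    times: np.ndarray            # minutes (same grid as the noisy series)
    our_total: np.ndarray        # mg O2/(L h), noiseless
    our_ss: np.ndarray           # Ss-driven exogenous component
    our_hyd: np.ndarray          # hydrolysis-driven exogenous component
    our_en: float                # endogenous level
    t1_star: float | None
    t2_star: float | None
    rbcod_star: float
    sbcod_star: float


@dataclass(frozen=True)
class SimulatedRespirogram:
    config: SimulationConfig
    our_series: OURSeries
    truth: RespirogramTruth
    do_trace: DOTrace | None = None


def _rates(ss, xs, c: SimulationConfig):
    """(uptake, hydrolysis) in mg COD/(L d)."""
    ss = max(ss, 0.0)
    xs = max(xs, 0.0)
    uptake = (c.mu_max / c.y_h) * ss / (c.k_s + ss) * c.x_h
    ratio = xs / c.x_h
    hyd = c.k_h * c.x_h * ratio / (ratio + c.k_x) * c.k_i / (c.k_i + ss)
    return uptake, hyd


def simulate_respirogram(config: SimulationConfig) -> SimulatedRespirogram:
    """Integrate the batch model and sample a (noisy) OUR series."""
    c = config

    def rhs(_t, y):
        uptake, hyd = _rates(y[0], y[1], c)
        return [-uptake + hyd, -hyd]

    t_end_d = c.duration_min / 1440.0
    t_min = np.arange(0.0, c.duration_min + 1e-9, c.sample_interval_min)
    sol = solve_ivp(rhs, (0.0, t_end_d), [c.ss0, c.xs0],
                    t_eval=t_min / 1440.0, method="LSODA",
                    rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(
            f"stiff integration failed ({sol.message}); config: {c}"
        )
    ss, xs = np.clip(sol.y[0], 0.0, None), np.clip(sol.y[1], 0.0, None)

    uptake = np.empty_like(ss)
    hyd = np.empty_like(ss)
    for i, (s, x) in enumerate(zip(ss, xs)):
        uptake[i], hyd[i] = _rates(s, x, c)
    our_en = 1.42 * c.b_h * c.x_h / 24.0
    our_ex = (1.0 - c.y_h) * uptake / 24.0
    our_hyd = (1.0 - c.y_h) * np.minimum(hyd, uptake) / 24.0
    our_ss = our_ex - our_hyd
    our_total = our_ex + our_en

    t1 = _first_time(t_min, (our_ss < 0.05 * our_hyd) & (our_hyd > 0))
    t2 = _first_time(t_min, our_ex < 0.02 * our_en)

    rng = np.random.default_rng(c.seed)
    noisy = our_total.copy()
    if c.noise_sd_frac > 0:
        sd = c.noise_sd_frac * float(our_total.max())
        noisy = np.clip(noisy + rng.normal(0.0, sd, size=noisy.shape),
                        0.0, None)

    truth = RespirogramTruth(times=t_min, our_total=our_total,
                             our_ss=our_ss, our_hyd=our_hyd,
                             our_en=our_en, t1_star=t1, t2_star=t2,
                             rbcod_star=c.ss0, sbcod_star=c.xs0)
    series = OURSeries(t_min, noisy, label=f"simulated(seed={c.seed})")
    return SimulatedRespirogram(config=c, our_series=series, truth=truth)


def _first_time(t: np.ndarray, mask: np.ndarray) -> float | None:
    idx = np.flatnonzero(mask)
    return float(t[idx[0]]) if len(idx) else None


def emit_do_trace(resp: SimulatedRespirogram,
                  config: SimulationConfig | None = None) -> DOTrace:
    """Emit a sealed-cycle DO trace driven by the noiseless OUR curve.

    Within each cycle DO declines from ``do_start`` at the instantaneous
    OUR; if the decline would push DO below 0 the trace is floored and a
    warning raised.
    """
    c = config or resp.config
    cycle_min, sample_s, do_start = c.do_cycle
    t = resp.truth.times
    our = resp.truth.our_total
    cycles = []
    floored = False
    start = 0.0
    while start + cycle_min <= t[-1] + 1e-9:
        s = np.arange(0.0, cycle_min * 60.0 + 1e-9, sample_s)
        our_inst = np.interp(start + s / 60.0, t, our)  # mg O2/(L h)
        # cumulative trapezoid of OUR over the cycle, seconds -> hours
        drop = np.concatenate([
            [0.0],
            np.cumsum((our_inst[1:] + our_inst[:-1]) / 2.0 * np.diff(s))
        ]) / 3600.0
        do = do_start - drop
        if np.any(do < 0):
            floored = True
            do = np.clip(do, 0.0, None)
        cycles.append(Cycle(start_time_min=start, elapsed_s=s, do_conc=do))
        start += cycle_min
    if floored:
        warnings.warn("DO would fall below 0 within a cycle; floored at 0",
                      RuntimeWarning, stacklevel=2)
    return DOTrace(cycles=tuple(cycles))


def scenario_s0x0(ratio: float, base: SimulationConfig) -> SimulationConfig:
    """Rescale (ss0 + xs0) to a target S0/X0 ratio (mg COD/mg VSS).

    The biomass VSS is x_h / 1.42; the ss0:xs0 proportion is preserved.
    """
    if ratio <= 0:
        raise ValueError("ratio must be strictly positive")
    vss = base.x_h / COD_TO_VSS
    total = base.ss0 + base.xs0
    if total <= 0:
        raise ValueError("base config has no substrate to scale")
    target = ratio * vss
    f = target / total
    return replace(base, ss0=base.ss0 * f, xs0=base.xs0 * f)
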