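"""Surface-limited hydrolysis kinetics for the SBCOD degradation stage.

Slowly biodegradable COD (Xs) is hydrolysed by heterotrophic biomass (X_H)
following the ASM-style saturating rate law

    dXs/dt = -k_h * X_H * (Xs/X_H) / (Xs/X_H + k_x)

with k_h the maximum specific hydrolysis rate (g COD_Xs / (g COD_XH * d))
and k_x the half-saturation (switching) constant of the hydrolysis surface
reaction (g COD_Xs / g COD_XH). Note the source rate law prints a single
symbol in both roles, which is dimensionally inconsistent; a distinct k_x
is used here. Because hydrolysis limits substrate supply, the exogenous
oxygen uptake tracks the hydrolysis rate:

    OUR_ex(t) = (1 - Y_H) * (-dXs/dt)

expressed in mg O2/(L*h) (internal rate units are per day; divide by 24).

X_H is not identifiable from a single OUR window (it enters only through
products and ratios), so it is a fixed input, by default derived from
MLVSS ~ 2000 mg/L with a COD-to-VSS factor of 1.42. The endogenous
baseline OUR_en must be subtracted by the caller before fitting: the rate
law describes exogenous respiration only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import lambertw

from .core import OURSeries

__all__ = [
    "HydrolysisParams",
    "HydrolysisFit",
    "hydrolysis_our",
    "fit_hydrolysis",
    "detect_sbcod_start",
    "default_x_h",
]

#: Multi-start optimizer seed.
FIT_SEED = 20210112

COD_TO_VSS = 1.42


def default_x_h(mlvss_mg_l: float = 2000.0,
                cod_to_vss: float = COD_TO_VSS) -> float:
    """Heterotrophic biomass as COD from an MLVSS measurement."""
    return mlvss_mg_l * cod_to_vss


@dataclass(frozen=True)
class HydrolysisParams:
    """Parameters of the hydrolysis stage.

    k_h : g COD_Xs/(g COD_XH * d); k_x : g COD_Xs/g COD_XH;
    x_h : mg COD/L; y_h : g/g; xs0 : mg COD/L at the window start;
    our_en : mg O2/(L*h) endogenous baseline.
    """

    k_h: float
    k_x: float
    x_h: float
    xs0: float
    y_h: float = 0.68
    our_en: float = 0.0

    def __post_init__(self):
        for name in ("k_h", "k_x", "x_h", "xs0"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0 or (v == 0 and name != "xs0"):
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.y_h < 1):
            raise ValueError("y_h must lie in (0, 1)")
        if not np.isfinite(self.our_en) or self.our_en < 0:
            raise ValueError("our_en must be finite and non-negative")


@dataclass(frozen=True)
class HydrolysisFit:
    """Result of fitting the hydrolysis rate law to an OUR window."""

    params: HydrolysisParams
    window: tuple[float, float]
    times: np.ndarray
    observed_ex: np.ndarray
    predicted_ex: np.ndarray
    residuals: np.ndarray
    rmse: float
    relative_rmse: float
    converged: bool


def _xs_rate(xs: float, k_h: float, k_x: float, x_h: float) -> float:
    """-dXs/dt in mg COD/(L*d)."""
    ratio = xs / x_h
    return k_h * x_h * ratio / (ratio + k_x)


def _w_exp(z: np.ndarray) -> np.ndarray:
    """Principal Lambert W of exp(z), evaluated safely for any real z.

    For moderate z the scipy routine is used directly; for large z (where
    exp overflows) the asymptotic expansion W(e^z) ~ z - ln z + ln z / z
    is refined by Newton steps on w + ln w = z.
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = z < 600.0
    out[small] = np.real(lambertw(np.exp(z[small])))
    big = ~small
    if np.any(big):
        zb = z[big]
        w = zb - np.log(zb) + np.log(zb) / zb
        for _ in range(4):  # Newton on f(w) = w + ln w - z
            w = w - (w + np.log(w) - zb) / (1.0 + 1.0 / w)
        out[big] = w
    return out


def _solve_xs(t_min: np.ndarray, params: HydrolysisParams) -> np.ndarray:
    """Xs(t) on a minutes grid, starting from the grid's first point.

    The saturating rate law separates: with K = k_x * x_h,
    (xs0 - Xs) + K ln(xs0/Xs) = k_h * x_h * tau, so
    Xs(tau) = K * W((xs0/K) * exp((xs0 - k_h*x_h*tau)/K)).
    """
    t_d = (np.asarray(t_min, float) - t_min[0]) / 1440.0
    if params.xs0 == 0.0:
        return np.zeros_like(t_d)
    cap = params.k_x * params.x_h
    a = params.k_h * params.x_h * t_d
    z = np.log(params.xs0 / cap) + (params.xs0 - a) / cap
    return np.clip(cap * _w_exp(z), 0.0, None)


def hydrolysis_our(t_min, params: HydrolysisParams) -> np.ndarray:
    """Predicted exogenous OUR (mg O2/(L*h)) on an increasing minutes grid."""
    t = np.asarray(t_min, dtype=float)
    if t.ndim != 1 or len(t) < 1:
        raise ValueError("time grid must be a non-empty 1-D array")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    xs = _solve_xs(t, params)
    rate_per_day = np.array(
        [_xs_rate(x, params.k_h, params.k_x, params.x_h) for x in xs]
    )
    return (1.0 - params.y_h) * rate_per_day / 24.0


def _window_slice(series: OURSeries, window) -> slice:
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window must satisfy t_start < t_end")
    idx = np.flatnonzero((series.times >= t0 - 1e-9) & (series.times <= t1 + 1e-9))
    if len(idx) == 0:
        raise ValueError("window contains no samples")
    return slice(int(idx[0]), int(idx[-1]) + 1)


def fit_hydrolysis(series: OURSeries, window, our_en: float,
                   y_h: float = 0.68, x_h: float | None = None,
                   init: HydrolysisParams | None = None,
                   n_starts: int = 5, seed: int = FIT_SEED) -> HydrolysisFit:
    """Fit (k_h, k_x, xs0) to the baseline-subtracted OUR in a time window.

    Least squares in log-parameterization (positivity by construction),
    multi-started from ``n_starts`` log-spaced initializations plus an
    optional user ``init``; the best optimum wins. ``converged`` reflects
    the winning optimizer status.
    """
    if x_h is None:
        x_h = default_x_h()
    sl = _window_slice(series, window)
    t = series.times[sl]
    if len(t) < 4:
        raise ValueError("hydrolysis fitting needs at least 4 points in window")
    obs_ex = np.clip(series.our[sl] - our_en, 0.0, None)
    if np.all(obs_ex == 0.0):
        raise ValueError("window is at endogenous baseline: nothing to fit")

    mean_obs = float(obs_ex.mean())
    # scale-informed starting grids
    rng = np.random.default_rng(seed)
    peak = float(obs_ex.max())
    span_h = (t[-1] - t[0]) / 60.0
    # rough magnitudes: total oxygen ~ peak*span -> xs0 ~ area/(1-y_h)
    area_guess = max(peak * span_h, 1e-6)
    xs0_guess = area_guess / (1.0 - y_h)
    kh_guess = peak * 24.0 / ((1.0 - y_h) * x_h)

    def predict(log_p):
        k_h, k_x, xs0 = np.exp(np.clip(log_p, -40.0, 40.0))
        p = HydrolysisParams(k_h=k_h, k_x=k_x, x_h=x_h, xs0=xs0, y_h=y_h)
        return hydrolysis_our(t, p)

    def resid(log_p):
        return predict(log_p) - obs_ex

    starts = []
    if init is not None:
        starts.append(np.log([init.k_h, init.k_x, init.xs0]))
    for mult in np.logspace(-1, 1, n_starts):
        starts.append(np.log([
            max(kh_guess * mult, 1e-8),
            max(0.03 * mult, 1e-8),
            max(xs0_guess * mult ** rng.uniform(0.2, 0.8), 1e-8),
        ]))

    best = None
    for s0 in starts:
        try:
            res = least_squares(resid, s0, method="lm", xtol=1e-12,
                                ftol=1e-12, max_nfev=400)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("hydrolysis fit failed from every start")

    k_h, k_x, xs0 = np.exp(best.x)
    params = HydrolysisParams(k_h=k_h, k_x=k_x, x_h=x_h, xs0=xs0,
                              y_h=y_h, our_en=our_en)
    pred = hydrolysis_our(t, params)
    residuals = obs_ex - pred
    rmse = float(np.sqrt(np.mean(residuals ** 2)))
    return HydrolysisFit(
        params=params, window=(float(t[0]), float(t[-1])), times=t,
        observed_ex=obs_ex, predicted_ex=pred, residuals=residuals,
        rmse=rmse,
        relative_rmse=rmse / mean_obs if mean_obs > 0 else np.inf,
        converged=bool(best.status > 0),
    )


def detect_sbcod_start(series: OURSeries, t2: float, our_en: float,
                       rel_tol: float = 0.10, y_h: float = 0.68,
                       x_h: float | None = None,
                       resid_z_max: float = 4.0,
                       noise_sd: float = 0.0,
                       noise_z: float = 2.0):
    """Locate the SBCOD-stage start t1 by backward window extension.

    Starting from the 4 points immediately before ``t2``, earlier points
    are prepended one at a time and the hydrolysis law refitted. Extension
    stops at "fitting distortion": the first window whose RMSE exceeds
    ``max(rel_tol * mean(OUR_ex,obs), noise_z * noise_sd)`` or whose newly
    added point has a standardized residual above ``resid_z_max``. The
    ``noise_sd`` floor (typically the standard deviation of the endogenous
    plateau about its mean) keeps the rule meaningful on noisy sensors: a
    fit cannot be expected to track the data more closely than the sensor
    scatter, so relative RMSE alone would reject conforming windows whose
    signal sits near the noise floor. t1 is the time of the earliest point
    whose inclusion kept the fit within tolerance. Returns ``(t1, fits)``
    with every attempted fit for audit.
    """
    times = series.times
    before = np.flatnonzero(times < t2 - 1e-9)
    if len(before) < 4:
        raise ValueError("need at least 4 points before t2")
    end = int(before[-1])
    start = end - 3

    def fit_from(i0):
        return fit_hydrolysis(series, (times[i0], times[end]), our_en,
                              y_h=y_h, x_h=x_h)

    def ok(fit: HydrolysisFit, new_point: bool) -> bool:
        floor = noise_z * noise_sd
        limit = max(rel_tol * float(fit.observed_ex.mean()), floor)
        if not np.isfinite(fit.rmse) or fit.rmse > limit:
            return False
        if new_point and len(fit.residuals) > 3:
            others = fit.residuals[1:]
            scale = max(float(np.std(others, ddof=1)), noise_sd)
            if scale > 0 and abs(fit.residuals[0]) / scale > resid_z_max:
                return False
        return True

    fits = [fit_from(start)]
    if not ok(fits[0], new_point=False):
        raise ValueError("no hydrolysis-conforming segment before t2")
    while start > 0:
        cand = fit_from(start - 1)
        fits.append(cand)
        if not ok(cand, new_point=True):
            # distortion must be systematic, not one aberrant sample: the
            # stop stands only if extending one point further also fails
            if start - 2 < 0:
                break
            cand2 = fit_from(start - 2)
            fits.append(cand2)
            if not ok(cand2, new_point=True):
                break
            start -= 2
            continue
        start -= 1
    return float(times[start]), fits
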