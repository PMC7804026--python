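"""Core containers for respirometric data.

Units follow the respirometry convention throughout the package: time in
minutes, oxygen uptake rate (OUR) in mg O2/(L*h), COD in mg/L. Integrations
convert minutes to hours internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when input data violates a container invariant."""


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class OURSeries:
    """An oxygen-uptake-rate curve OUR(t).

    Parameters
    ----------
    times : array-like
        Sample times in minutes, strictly increasing, length >= 3.
    our : array-like
        OUR values in mg O2/(L*h), non-negative, same length as ``times``.
    label : str
        Free-text description of the series.
    """

    times: np.ndarray
    our: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = _as_float_vector(self.times, "times")
        y = _as_float_vector(self.our, "our")
        if len(t) != len(y):
            raise ValidationError("times and our must have equal length")
        if len(t) < 3:
            raise ValidationError("an OUR series needs at least 3 points")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValidationError("OUR values must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "our", y)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class CODSeries:
    """COD concentration over time for one filter fraction or the mixture."""

    times: np.ndarray
    cod: np.ndarray
    fraction_label: str = "mixed-liquor"

    _LABELS = ("TCOD", "PCOD", "CCOD", "SCOD", "mixed-liquor")

    def __post_init__(self):
        t = _as_float_vector(self.times, "times")
        c = _as_float_vector(self.cod, "cod")
        if len(t) != len(c):
            raise ValidationError("times and cod must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValidationError("COD values must be non-negative")
        if self.fraction_label not in self._LABELS:
            raise ValidationError(
                f"fraction_label must be one of {self._LABELS}"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cod", c)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Cycle:
    """One sealed measurement cycle of the batch respirometer."""

    start_time_min: float
    elapsed_s: np.ndarray
    do_conc: np.ndarray

    def __post_init__(self):
        t = _as_float_vector(self.elapsed_s, "elapsed_s")
        d = _as_float_vector(self.do_conc, "do_conc")
        if len(t) != len(d):
            raise ValidationError("elapsed_s and do_conc must have equal length")
        if len(t) < 3:
            raise ValidationError("a cycle needs at least 3 samples")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                "elapsed_s must be strictly increasing within a cycle"
            )
        if np.any(d < 0):
            raise ValidationError("DO concentrations must be non-negative")
        object.__setattr__(self, "elapsed_s", t)
        object.__setattr__(self, "do_conc", d)


@dataclass(frozen=True)
class DOTrace:
    """Dissolved-oxygen record of repeated sealed cycles.

    The respirometer reseals the vessel every few minutes and logs DO at a
    fixed cadence (typically every 10 s); the within-cycle DO decline slope
    is the oxygen uptake rate.
    """

    cycles: tuple[Cycle, ...]
    temperature_c: float | None = None
    ph: float | None = None
    mlvss_mg_l: float | None = None

    def __post_init__(self):
        cyc = tuple(self.cycles)
        if not cyc:
            raise ValidationError("a DO trace needs at least one cycle")
        starts = [c.start_time_min for c in cyc]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValidationError(
                "cycle start times must be strictly increasing"
            )
        object.__setattr__(self, "cycles", cyc)

    def __len__(self) -> int:
        return len(self.cycles)
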