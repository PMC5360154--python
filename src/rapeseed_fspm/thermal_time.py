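"""Thermal time (growing degree days) from day/night chamber regimes.

A growth-chamber regime is a square wave: the day temperature holds during
the photoperiod, the night temperature for the rest of the 24 h. The daily
thermal-time increment is the time-weighted mean temperature minus a base
temperature (5 °C for oilseed rape, below which extension growth stops),
clamped at zero. All downstream growth curves are functions of the
accumulated temperature since transfer into the chamber, in °Cd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TemperatureRegime",
    "ThermalTimeSeries",
    "PRESETS",
    "daily_increment",
    "reported_increment",
    "accumulate",
]


class InvalidRegimeError(ValueError):
    """Raised when a temperature regime fails validation."""


@dataclass(frozen=True)
class TemperatureRegime:
    """Square-wave day/night temperature regime of a growth chamber.

    Parameters
    ----------
    t_night, t_day : float
        Night and day air temperatures, °C. ``t_day >= t_night`` is typical
        but not required.
    photoperiod_h : float
        Hours per 24 h at the day temperature (and with lights on).
    t_base : float
        Base temperature for thermal-time accumulation, °C. Default 5.
    """

    t_night: float
    t_day: float
    photoperiod_h: float = 14.0
    t_base: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.photoperiod_h <= 24.0:
            raise InvalidRegimeError(
                f"photoperiod_h must lie in [0, 24], got {self.photoperiod_h!r}"
            )


#: Named chamber regimes: high (26/30 °C), medium (18/22 °C), low (10/14 °C)
#: night/day temperatures, all with a 14-h photoperiod and 5 °C base.
PRESETS: dict[str, TemperatureRegime] = {
    "H": TemperatureRegime(t_night=26.0, t_day=30.0),
    "M": TemperatureRegime(t_night=18.0, t_day=22.0),
    "L": TemperatureRegime(t_night=10.0, t_day=14.0),
}


@dataclass(frozen=True)
class ThermalTimeSeries:
    """Accumulated temperature since transfer, one entry per day.

    ``ts[k]`` is the accumulated temperature (°Cd) at the end of day ``k``;
    ``ts[0] = 0`` at transfer. Non-decreasing by construction.
    """

    day_index: np.ndarray
    ts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "day_index", np.asarray(self.day_index, dtype=int))
        object.__setattr__(self, "ts", np.asarray(self.ts, dtype=float))

    def __len__(self) -> int:
        return len(self.ts)


def daily_increment(regime: TemperatureRegime) -> float:
    """Daily thermal-time increment in °Cd d⁻¹, unrounded.

    ``max(0, (t_night*(24-p) + t_day*p)/24 - t_base)`` with photoperiod
    ``p`` in hours. Clamped at zero: temperatures below the base add nothing.
    """
    p = regime.photoperiod_h
    mean_t = (regime.t_night * (24.0 - p) + regime.t_day * p) / 24.0
    return max(0.0, mean_t - regime.t_base)


def reported_increment(regime: TemperatureRegime) -> int:
    """The increment rounded half-up to the nearest integer °Cd d⁻¹.

    Reporting convention only; internal arithmetic keeps the unrounded
    value (the three preset regimes report 23, 15 and 7).
    """
    import math

    return math.floor(daily_increment(regime) + 0.5)


def accumulate(regime: TemperatureRegime, n_days: int) -> ThermalTimeSeries:
    """Accumulated-temperature series over ``n_days`` days after transfer.

    Returns a series of length ``n_days + 1`` starting at 0 with a constant
    daily step of :func:`daily_increment`.
    """
    if n_days < 0:
        raise ValueError(f"n_days must be >= 0, got {n_days}")
    days = np.arange(n_days + 1)
    return ThermalTimeSeries(day_index=days, ts=days * daily_increment(regime))
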