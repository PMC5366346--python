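"""Thermal time from air temperature via a beta response function.

Development-effective time is accumulated as

    TT = integral of max(0, (T_ref - T_base) * f(T)) dt        [degree-days]

with the beta response

    f(T) = ((T - T_min)/(T_ref - T_min))^q * ((T_max - T)/(T_max - T_ref))

which equals 1 at the reference temperature (20 deg C) and 0 at or beyond the
cardinal temperatures ``T_min`` / ``T_max``.  ``T_base`` (5 deg C) scales one
day at the reference temperature to 15 degree-days.  Axis-local development is
expressed in *phyllochronic time* -- thermal time divided by the axis
phyllochron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigurationError, DataValidationError, WindowError

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class BetaThermalParams:
    """Cardinal temperatures and shape of the beta development response.

    ``t_min``/``t_max`` bound the range in which development occurs, ``q``
    shapes the ascending branch; ``t_ref`` (20 deg C) and ``t_base`` (5 deg C)
    are fixed scaling temperatures.
    """

    t_min: float = 0.0
    t_max: float = 40.0
    q: float = 1.5
    t_ref: float = 20.0
    t_base: float = 5.0

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_ref < self.t_max):
            raise ConfigurationError(
                f"require t_min < t_ref < t_max, got {self.t_min}, {self.t_ref}, {self.t_max}"
            )
        if self.q <= 0:
            raise ConfigurationError(f"shape parameter q must be positive, got {self.q}")
        if self.t_base >= self.t_ref:
            raise ConfigurationError(
                f"require t_base < t_ref, got t_base={self.t_base}, t_ref={self.t_ref}"
            )


def beta_response(temp_c, params: BetaThermalParams):
    """Dimensionless beta response f(T); 0 outside (t_min, t_max), 1 at t_ref."""
    t = np.asarray(temp_c, dtype=float)
    inside = (t > params.t_min) & (t < params.t_max)
    tt = np.where(inside, t, params.t_ref)  # placeholder to keep powers real
    rise = ((tt - params.t_min) / (params.t_ref - params.t_min)) ** params.q
    fall = (params.t_max - tt) / (params.t_max - params.t_ref)
    out = np.where(inside, rise * fall, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def development_rate(temp_c, params: BetaThermalParams):
    """Instantaneous thermal-time accumulation rate in degree-days per day."""
    return np.maximum(0.0, (params.t_ref - params.t_base) * beta_response(temp_c, params))


class TemperatureSeries:
    """An air-temperature record: strictly increasing times (days) + deg C.

    ``days`` are float days from an arbitrary origin (day = 86 400 s, no
    timezone semantics); ``origin`` optionally keeps the absolute timestamp of
    day 0 for CSV round trips.
    """

    __slots__ = ("days", "temp_c", "origin")

    def __init__(self, days, temp_c, origin: pd.Timestamp | None = None):
        self.days = np.asarray(days, dtype=float)
        self.temp_c = np.asarray(temp_c, dtype=float)
        self.origin = origin
        if self.days.ndim != 1 or self.days.size < 1:
            raise DataValidationError("temperature series needs at least one record")
        if self.days.size != self.temp_c.size:
            raise DataValidationError("days and temp_c must have equal length")
        if self.days.size > 1 and not np.all(np.diff(self.days) > 0):
            raise DataValidationError("timestamps must be strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.days[0]), float(self.days[-1])

    def __len__(self) -> int:
        return int(self.days.size)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TemperatureSeries":
        if "temp_c" not in frame.columns:
            raise DataValidationError("temperature table must have a 'temp_c' column")
        if "timestamp" in frame.columns:
            ts = pd.to_datetime(frame["timestamp"])
            origin = ts.iloc[0]
            days = (ts - origin).dt.total_seconds().to_numpy() / SECONDS_PER_DAY
            return cls(days, frame["temp_c"].to_numpy(), origin=origin)
        if "day" in frame.columns:
            return cls(frame["day"].to_numpy(), frame["temp_c"].to_numpy())
        raise DataValidationError("temperature table needs a 'timestamp' or 'day' column")

    @classmethod
    def from_csv(cls, path) -> "TemperatureSeries":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        origin = self.origin if self.origin is not None else pd.Timestamp("2000-01-01")
        stamps = origin + pd.to_timedelta(self.days, unit="D")
        return pd.DataFrame({"timestamp": stamps.strftime("%Y-%m-%dT%H:%M:%S"),
                             "temp_c": self.temp_c})


def thermal_time(series: TemperatureSeries, params: BetaThermalParams,
                 t0: float | None = None, t1: float | None = None) -> float:
    """Thermal time (degree-days) accumulated over ``[t0, t1]`` (days).

    Trapezoidal integration on the recorded timestamps; the rate is evaluated
    at each record and interpolated linearly at the window edges, which makes
    the integral exactly additive over adjacent windows.
    """
    lo, hi = series.span
    t0 = lo if t0 is None else float(t0)
    t1 = hi if t1 is None else float(t1)
    eps = 1e-9
    if t0 > t1:
        raise WindowError(f"window start {t0} exceeds end {t1}")
    if t0 < lo - eps or t1 > hi + eps:
        raise WindowError(f"window [{t0}, {t1}] outside recorded span [{lo}, {hi}]")
    if t0 == t1:
        return 0.0
    rate = development_rate(series.temp_c, params)
    inner = series.days[(series.days > t0) & (series.days < t1)]
    xs = np.concatenate(([t0], inner, [t1]))
    rs = np.interp(xs, series.days, rate)
    return float(np.trapezoid(rs, xs))


def cumulative_thermal_time(series: TemperatureSeries, params: BetaThermalParams) -> np.ndarray:
    """Cumulative thermal time (degree-days) at each recorded timestamp."""
    rate = development_rate(series.temp_c, params)
    if len(series) == 1:
        return np.zeros(1)
    return cumulative_trapezoid(rate, series.days, initial=0.0)


def phyllochronic_time(tt_since_axis_start, phyllochron: float):
    """Convert thermal time on an axis into phyllochrons of that axis."""
    if phyllochron <= 0:
        raise ConfigurationError(f"phyllochron must be positive, got {phyllochron}")
    out = np.asarray(tt_since_axis_start, dtype=float) / phyllochron
    if out.ndim == 0:
        return float(out)
    return out
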