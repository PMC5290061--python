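"""Soil-climate driving variables.

The simulation is driven by an hourly soil-temperature profile (one value per
1-cm depth layer, 1..100 cm, starting at Julian day 1, 00:00) and by an hourly
volumetric water-content series at sowing depth covering the germination
window.  Profiles for real sites are normally produced by a soil hydrology
model and supplied as files; for testing and self-contained runs this module
also generates a synthetic but physically plausible profile from a damped
sinusoidal annual + diel cycle.

Hour indexing is 0-based from Julian day 1, 00:00; ``julian_day = hour // 24
+ 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

N_DEPTHS = 100  # depth layers, 1..100 cm
HOURS_PER_DAY = 24


class ClimateFormatError(ValueError):
    """Raised when a climate file is malformed or has gaps.

    Attributes ``missing_depth`` / ``missing_hour`` name the first gap found.
    """

    def __init__(self, message: str, *, missing_depth: int | None = None,
                 missing_hour: int | None = None):
        super().__init__(message)
        self.missing_depth = missing_depth
        self.missing_hour = missing_hour


def hour_to_julian_day(hour: int) -> int:
    return hour // HOURS_PER_DAY + 1


def day_hour_range(day: int) -> tuple[int, int]:
    """Half-open hour range [start, stop) covering Julian day ``day``."""
    start = (day - 1) * HOURS_PER_DAY
    return start, start + HOURS_PER_DAY


@dataclass
class TemperatureField:
    """Hourly soil temperature (°C) for depth layers 1..100 cm.

    ``values[h, z-1]`` is the temperature at hour ``h`` (0-based from Julian
    day 1, 00:00) and depth ``z`` cm.
    """

    values: np.ndarray  # shape (hours, N_DEPTHS)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_DEPTHS:
            raise ValueError(
                f"temperature field must have shape (hours, {N_DEPTHS}); "
                f"got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("temperature field contains non-finite values")

    @property
    def hours(self) -> int:
        return self.values.shape[0]

    def temperature_at(self, depth_cm: int, hour: int) -> float:
        """Exact lookup of the temperature at one depth layer and hour."""
        if not 1 <= depth_cm <= N_DEPTHS:
            raise IndexError(f"depth {depth_cm} cm outside 1..{N_DEPTHS}")
        if not 0 <= hour < self.hours:
            raise IndexError(f"hour {hour} outside 0..{self.hours - 1}")
        return float(self.values[hour, depth_cm - 1])

    def average_profile_temperature(self, hour_start: int, hour_stop: int) -> float:
        """Arithmetic mean over all 100 depth layers and [hour_start, hour_stop)."""
        if not (0 <= hour_start < hour_stop <= self.hours):
            raise IndexError(
                f"hour window [{hour_start}, {hour_stop}) outside field of "
                f"{self.hours} hours")
        return float(self.values[hour_start:hour_stop].mean())

    def daily_mean_profile_temperature(self, day: int) -> float:
        """Mean over all depths over the 24 hours of Julian day ``day``."""
        start, stop = day_hour_range(day)
        return self.average_profile_temperature(start, stop)

    def depth_series(self, depth_cm: int) -> np.ndarray:
        if not 1 <= depth_cm <= N_DEPTHS:
            raise IndexError(f"depth {depth_cm} cm outside 1..{N_DEPTHS}")
        return self.values[:, depth_cm - 1]


@dataclass
class MoistureSeries:
    """Hourly volumetric water content (%) at sowing depth from ``start_hour``.

    Queries past the end of the record hold the last observed value: the
    series is only required to cover the 2–3-week germination window, while
    emergence may in cold springs be resolved slightly later.
    """

    start_hour: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("moisture series must be a non-empty 1-D array")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValueError("water content must lie in [0, 100] %")

    def at_hour(self, hour: int) -> float:
        if hour < self.start_hour:
            raise IndexError(
                f"hour {hour} precedes moisture record start {self.start_hour}")
        idx = min(hour - self.start_hour, self.values.size - 1)
        return float(self.values[idx])


@dataclass
class ClimateConfig:
    """Parameters of the synthetic soil-climate generator.

    Temperature follows a damped-sinusoid conduction model,

        T(z, t) = mean + A_a e^{-z/d_a} sin(ω_year (t - phase) - z/d_a)
                       + A_d e^{-z/d_d} sin(ω_day t),

    with depth z in cm; the annual and diel waves are damped on separate
    characteristic depths.  Defaults emulate a temperate continental corn
    belt season.  Moisture is a baseline plus bounded Gaussian noise,
    clipped to [0, 100] %.
    """

    mean_temp_c: float = 11.0
    annual_amplitude_c: float = 14.0
    diel_amplitude_c: float = 3.0
    damping_depth_cm: float = 180.0
    diel_damping_depth_cm: float = 15.0
    phase_day: float = 109.0
    moisture_baseline_pct: float = 35.0
    moisture_noise_pct: float = 2.0
    moisture_start_day: int = 125
    moisture_days: int = 21
    n_days: int = 365
    seed: int = 0

    def validate(self) -> None:
        if self.annual_amplitude_c < 0 or self.diel_amplitude_c < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.damping_depth_cm <= 0 or self.diel_damping_depth_cm <= 0:
            raise ValueError("damping depths must be > 0")
        if not 0 <= self.moisture_baseline_pct <= 100:
            raise ValueError("moisture baseline must lie in [0, 100] %")
        if self.n_days < 1 or self.moisture_days < 1:
            raise ValueError("durations must be >= 1 day")


#: Drought preset: baseline below the 30 % germination threshold, so the
#: crop never emerges — used to exercise the failed-emergence pathway.
DROUGHT_MOISTURE_PCT = 25.0


def generate_synthetic_climate(
        cfg: ClimateConfig) -> tuple[TemperatureField, MoistureSeries]:
    """Deterministic (seeded) synthetic temperature field + moisture series."""
    cfg.validate()
    n_hours = cfg.n_days * HOURS_PER_DAY
    t = np.arange(n_hours, dtype=float)          # hours since day 1, 00:00
    day = t / HOURS_PER_DAY
    z = np.arange(1, N_DEPTHS + 1, dtype=float)  # cm

    omega_year = 2.0 * np.pi / 365.0             # per day
    omega_day = 2.0 * np.pi / HOURS_PER_DAY      # per hour

    zd_a = z / cfg.damping_depth_cm
    zd_d = z / cfg.diel_damping_depth_cm
    annual = (cfg.annual_amplitude_c * np.exp(-zd_a)[None, :]
              * np.sin(omega_year * (day[:, None] - cfg.phase_day)
                       - zd_a[None, :]))
    diel = (cfg.diel_amplitude_c * np.exp(-zd_d)[None, :]
            * np.sin(omega_day * t)[:, None])
    field_values = cfg.mean_temp_c + annual + diel
    temp = TemperatureField(field_values)

    rng = np.random.default_rng(cfg.seed)
    start_hour = (cfg.moisture_start_day - 1) * HOURS_PER_DAY
    n_wc = cfg.moisture_days * HOURS_PER_DAY
    wc = cfg.moisture_baseline_pct + cfg.moisture_noise_pct * rng.standard_normal(n_wc)
    wc = np.clip(wc, 0.0, 100.0)
    return temp, MoistureSeries(start_hour=start_hour, values=wc)


# ---------------------------------------------------------------------------
# File IO — long-format CSV, diff-able and streamable.
#   temperature: header `hour,depth_cm,temp_c`, one row per (hour, depth)
#   moisture:    header `hour,wc_pct`, one row per hour (absolute hour index)
# ---------------------------------------------------------------------------

def save_temperature_profile(field_: TemperatureField, path: str | Path) -> None:
    hours = np.repeat(np.arange(field_.hours), N_DEPTHS)
    depths = np.tile(np.arange(1, N_DEPTHS + 1), field_.hours)
    df = pd.DataFrame({"hour": hours, "depth_cm": depths,
                       "temp_c": field_.values.ravel()})
    df.to_csv(path, index=False)


def load_temperature_profile(path: str | Path) -> TemperatureField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"hour", "depth_cm", "temp_c"}
    if not required.issubset(df.columns):
        raise ClimateFormatError(
            f"temperature file must have columns {sorted(required)}; "
            f"got {list(df.columns)}")
    n_hours = int(df["hour"].max()) + 1
    depths_present = set(df["depth_cm"].unique().tolist())
    for z in range(1, N_DEPTHS + 1):
        if z not in depths_present:
            raise ClimateFormatError(
                f"temperature file is missing depth layer {z} cm",
                missing_depth=z)
    counts = df.groupby("hour").size()
    hours_present = set(counts.index.tolist())
    for h in range(n_hours):
        if h not in hours_present:
            raise ClimateFormatError(
                f"temperature file is missing hour {h}", missing_hour=h)
    if len(df) != n_hours * N_DEPTHS:
        bad = counts[counts != N_DEPTHS]
        h = int(bad.index[0])
        raise ClimateFormatError(
            f"hour {h} has {int(bad.iloc[0])} depth records, expected {N_DEPTHS}",
            missing_hour=h)
    values = (df.sort_values(["hour", "depth_cm"])["temp_c"]
              .to_numpy().reshape(n_hours, N_DEPTHS))
    return TemperatureField(values)


def save_moisture_series(series: MoistureSeries, path: str | Path) -> None:
    hours = series.start_hour + np.arange(series.values.size)
    pd.DataFrame({"hour": hours, "wc_pct": series.values}).to_csv(path, index=False)


def load_moisture_series(path: str | Path) -> MoistureSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"hour", "wc_pct"}.issubset(df.columns):
        raise ClimateFormatError(
            f"moisture file must have columns ['hour', 'wc_pct']; "
            f"got {list(df.columns)}")
    df = df.sort_values("hour")
    hours = df["hour"].to_numpy()
    if hours.size == 0:
        raise ClimateFormatError("moisture file is empty")
    gaps = np.flatnonzero(np.diff(hours) != 1)
    if gaps.size:
        raise ClimateFormatError(
            f"moisture file is missing hour {int(hours[gaps[0]]) + 1}",
            missing_hour=int(hours[gaps[0]]) + 1)
    return MoistureSeries(start_hour=int(hours[0]),
                          values=df["wc_pct"].to_numpy())
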