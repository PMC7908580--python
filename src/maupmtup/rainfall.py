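"""Synthetic gridded daily rainfall with Southern-Hemisphere seasonality.

The deterministic annual cycle is a sinusoid peaking in mid-July (austral
winter) and troughing in mid-January, calibrated so that the June-August and
December-February daily means equal the configured winter and summer values.
On top of the cycle sit two stochastic components: an interannual anomaly
(one multiplicative log-normal factor per calendar month, shared across the
grid, mimicking the large year-to-year swings of annual totals in semi-arid
regions) and independent additive Gaussian noise per cell-day, truncated at
zero.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Day of year at the centre of the winter peak (mid-July).
_PEAK_DOY = 196.5


@dataclass
class RainfallField:
    """Daily precipitation (mm) on a grid: ``values[day, cell]``."""

    dates: pd.DatetimeIndex
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.dates), len(self.cell_ids)):
            raise ValueError("values must have shape (n_days, n_cells)")
        if np.any(self.values < 0):
            raise ValueError("rainfall values must be non-negative")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 1):
            raise ValueError("dates must be consecutive calendar days")

    def mean_over(self, start: datetime.date, end: datetime.date) -> np.ndarray:
        """Per-cell mean daily rainfall over the closed interval [start, end]."""
        mask = (self.dates >= pd.Timestamp(start)) & (self.dates <= pd.Timestamp(end))
        if not mask.any():
            raise ValueError(f"no rainfall data in [{start}, {end}]")
        return self.values[mask].mean(axis=0)


def _seasonal_cycle(dates: pd.DatetimeIndex, summer_mm: float, winter_mm: float) -> np.ndarray:
    """Sinusoid through the year hitting the stated seasonal window means."""
    phase = 2.0 * np.pi * (dates.dayofyear.to_numpy() - _PEAK_DOY) / 365.25
    # calibrate the amplitude against the actual Jun-Aug window of the cosine
    ref = pd.date_range("2001-06-01", "2001-08-31", freq="D")
    g = np.cos(2.0 * np.pi * (ref.dayofyear.to_numpy() - _PEAK_DOY) / 365.25).mean()
    c0 = 0.5 * (winter_mm + summer_mm)
    c1 = 0.0 if winter_mm == summer_mm else 0.5 * (winter_mm - summer_mm) / g
    return c0 + c1 * np.cos(phase)


def gen_rainfall(
    start_date: datetime.date,
    end_date: datetime.date,
    cells: Sequence[str],
    seasonal_means: tuple[float, float] = (0.43, 1.50),
    noise_sd: float = 0.5,
    seed: int = 0,
    month_anomaly_sd: float = 0.0,
) -> RainfallField:
    """Generate a daily rainfall field.

    Parameters
    ----------
    seasonal_means
        ``(summer_mm, winter_mm)`` target daily means for December-February
        and June-August respectively.
    noise_sd
        Standard deviation (mm) of the additive per-cell-day noise; negative
        draws are truncated to zero.
    month_anomaly_sd
        Log-scale SD of a per-calendar-month multiplicative anomaly shared
        across cells (mean-one log-normal); 0 disables interannual variation.
    """
    if end_date < start_date:
        raise ValueError("end_date must not precede start_date")
    summer_mm, winter_mm = seasonal_means
    if summer_mm < 0 or winter_mm < 0:
        raise ValueError("seasonal means must be non-negative")

    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, end_date, freq="D")
    base = _seasonal_cycle(dates, summer_mm, winter_mm)

    if month_anomaly_sd > 0:
        months = pd.PeriodIndex(dates, freq="M")
        uniq = months.unique()
        fac = np.exp(
            rng.normal(-0.5 * month_anomaly_sd**2, month_anomaly_sd, size=len(uniq))
        )
        base = base * fac[np.searchsorted(uniq.asi8, months.asi8)]

    values = np.tile(base[:, None], (1, len(cells)))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.maximum(values, 0.0)
    return RainfallField(dates=dates, cell_ids=list(cells), values=values)
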