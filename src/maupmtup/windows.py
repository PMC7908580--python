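"""Temporal aggregation windows and their exposure-lag pairings.

An *arrangement* is one choice of (outcome-window endpoint month, rainfall
window length, lag).  Outcome windows are 12 calendar months long; the lag is
measured between the END of the rainfall window and the END of the outcome
window, so lag 0 means the rainfall window abuts the outcome window's end.
All intervals are closed ``[start, end]`` in whole calendar days.
"""

from __future__ import annotations

import calendar
import datetime
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

ENDPOINT_MONTHS: tuple[int, ...] = (2, 4, 6, 8, 10, 12)
MONTH_NAMES = {
    2: "February", 4: "April", 6: "June", 8: "August", 10: "October", 12: "December"
}
RAIN_LENGTHS: tuple[int, ...] = (3, 6)
LAGS: tuple[int, ...] = (0, 6, 12, 18, 24)
OUTCOME_LENGTH_MONTHS = 12


def _shift_month(year: int, month: int, delta: int) -> tuple[int, int]:
    m = (year * 12 + (month - 1)) + delta
    return m // 12, m % 12 + 1


def month_start(year: int, month: int) -> datetime.date:
    return datetime.date(year, month, 1)


def month_end(year: int, month: int) -> datetime.date:
    return datetime.date(year, month, calendar.monthrange(year, month)[1])


def _span_start(end_year: int, end_month: int, length: int) -> datetime.date:
    y, m = _shift_month(end_year, end_month, -(length - 1))
    return month_start(y, m)


@dataclass(frozen=True)
class WindowArrangement:
    """One (endpoint month, rainfall length, lag) temporal configuration."""

    endpoint_month: int
    rain_length_months: int
    lag_months: int
    outcome_length_months: int = OUTCOME_LENGTH_MONTHS

    def __post_init__(self) -> None:
        if self.endpoint_month not in ENDPOINT_MONTHS:
            raise ValueError(f"endpoint_month must be one of {ENDPOINT_MONTHS}")
        if self.rain_length_months not in RAIN_LENGTHS:
            raise ValueError(f"rain_length_months must be one of {RAIN_LENGTHS}")
        if self.lag_months not in LAGS:
            raise ValueError(f"lag_months must be one of {LAGS}")
        if self.outcome_length_months != OUTCOME_LENGTH_MONTHS:
            raise ValueError("outcome windows are fixed at 12 months")

    @property
    def label(self) -> str:
        return (
            f"{MONTH_NAMES[self.endpoint_month]} "
            f"{self.rain_length_months}, {self.lag_months}"
        )


@dataclass(frozen=True)
class WindowInstance:
    """A concrete outcome interval paired with its rainfall interval."""

    outcome_interval: tuple[datetime.date, datetime.date]
    rain_interval: tuple[datetime.date, datetime.date]

    @property
    def window_id(self) -> str:
        return self.outcome_interval[1].strftime("%Y-%m")

    @property
    def midpoint(self) -> datetime.date:
        a, b = self.outcome_interval
        return a + (b - a) / 2


def enumerate_outcome_windows(
    study_start: datetime.date,
    study_end: datetime.date,
    endpoint_month: int,
) -> list[tuple[datetime.date, datetime.date]]:
    """All 12-month windows ending on the last day of ``endpoint_month`` that
    lie entirely inside the study period, in chronological order."""
    if study_start >= study_end:
        raise ValueError("study_start must precede study_end")
    out = []
    for year in range(study_start.year, study_end.year + 1):
        end = month_end(year, endpoint_month)
        start = _span_start(year, endpoint_month, OUTCOME_LENGTH_MONTHS)
        if start >= study_start and end <= study_end:
            out.append((start, end))
    return out


def pair_rain_window(
    outcome: tuple[datetime.date, datetime.date],
    rain_length: int,
    lag: int,
) -> tuple[datetime.date, datetime.date]:
    """Rainfall interval ending ``lag`` months before the outcome's end month,
    spanning ``rain_length`` whole calendar months."""
    end = outcome[1]
    ry, rm = _shift_month(end.year, end.month, -lag)
    return (_span_start(ry, rm, rain_length), month_end(ry, rm))


def window_instances(
    study_start: datetime.date,
    study_end: datetime.date,
    arrangement: WindowArrangement,
) -> list[WindowInstance]:
    """Concrete (outcome, rainfall) interval pairs for one arrangement."""
    return [
        WindowInstance(
            outcome_interval=o,
            rain_interval=pair_rain_window(
                o, arrangement.rain_length_months, arrangement.lag_months
            ),
        )
        for o in enumerate_outcome_windows(study_start, study_end, arrangement.endpoint_month)
    ]


@dataclass(frozen=True)
class PreparationKey:
    """Descriptor of one data preparation (spatial x temporal x gender)."""

    endpoint_month: int
    rain_length_months: int
    lag_months: int
    zonation: str
    gender: str

    @property
    def arrangement(self) -> WindowArrangement:
        return WindowArrangement(
            self.endpoint_month, self.rain_length_months, self.lag_months
        )

    def __str__(self) -> str:
        return (
            f"e{self.endpoint_month:02d}_r{self.rain_length_months}"
            f"_l{self.lag_months:02d}_{self.zonation}_{self.gender}"
        )


def enumerate_preparations(
    endpoints: Sequence[int] = ENDPOINT_MONTHS,
    rain_lengths: Sequence[int] = RAIN_LENGTHS,
    lags: Sequence[int] = LAGS,
    zonations: Sequence[str] = ("base",),
    genders: Sequence[str] = ("female", "male"),
) -> list[PreparationKey]:
    """Full factorial product of the configured axes, in deterministic order
    (endpoints x rain lengths x lags x zonations x genders)."""
    return [
        PreparationKey(e, r, l, z, g)
        for e, r, l, z, g in itertools.product(
            endpoints, rain_lengths, lags, zonations, genders
        )
    ]
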