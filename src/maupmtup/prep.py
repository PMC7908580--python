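"""Data preparation: grid-to-area rainfall mapping, population interpolation
and aggregation of unit-level data into zone x window model rows.

A *preparation* is the dataset produced for one (zonation, temporal
arrangement, gender) combination: one row per zone per outcome window with
the event count ``y``, the interpolated population, the expected count ``e``
and the mean daily rainfall ``x`` over the zone's rainfall interval.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .rainfall import RainfallField


def map_grid_to_areas(field_: RainfallField, lattice) -> np.ndarray:
    """Area-weighted average of gridded rainfall onto the base units.

    Returns an array ``(n_days, n_units)``; a unit's daily value is the
    overlap-weight convex combination of the cell values for that day.
    """
    if list(field_.cell_ids) != list(lattice.cell_ids):
        known = set(field_.cell_ids)
        w = lattice.overlap_weights.tocoo()
        for unit, cell in zip(w.row, w.col):
            if lattice.cell_ids[cell] not in known:
                raise ValueError(
                    f"unit {unit} references rainfall cell "
                    f"{lattice.cell_ids[cell]!r} absent from the field"
                )
        # reorder field columns to the lattice's cell ordering
        order = [field_.cell_ids.index(c) for c in lattice.cell_ids]
        values = field_.values[:, order]
    else:
        values = field_.values
    return values @ lattice.overlap_weights.T.toarray()


def interpolate_population(
    census_dates: Sequence[datetime.date],
    pops: np.ndarray,
    window: tuple[datetime.date, datetime.date],
) -> np.ndarray:
    """Population at the window midpoint by piecewise-linear interpolation.

    Outside the census range the nearest census pair is extrapolated
    linearly; results are floored at zero.  ``pops`` is ``(n_units,
    n_censuses)`` aligned with ``census_dates``.
    """
    if len(census_dates) < 2:
        raise ValueError("at least two census dates are required")
    t = np.array([d.toordinal() for d in census_dates], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("census dates must be strictly increasing")
    pops = np.asarray(pops, dtype=float)
    start, end = window
    mid = (start + (end - start) / 2).toordinal()

    if mid <= t[0]:
        lo, hi = 0, 1
    elif mid >= t[-1]:
        lo, hi = len(t) - 2, len(t) - 1
    else:
        hi = int(np.searchsorted(t, mid, side="right"))
        lo = hi - 1
    frac = (mid - t[lo]) / (t[hi] - t[lo])
    out = pops[:, lo] + frac * (pops[:, hi] - pops[:, lo])
    return np.maximum(out, 0.0)


def unit_window_rainfall(
    unit_daily: np.ndarray,
    dates: pd.DatetimeIndex,
    intervals: Sequence[tuple[datetime.date, datetime.date]],
) -> np.ndarray:
    """Mean daily rainfall per unit over each closed interval.

    Returns ``(n_units, n_intervals)``.
    """
    out = np.empty((unit_daily.shape[1], len(intervals)))
    for j, (a, b) in enumerate(intervals):
        mask = (dates >= pd.Timestamp(a)) & (dates <= pd.Timestamp(b))
        if not mask.any():
            raise ValueError(f"rainfall series does not cover [{a}, {b}]")
        out[:, j] = unit_daily[mask].mean(axis=0)
    return out


def winter_exposure(
    unit_daily: np.ndarray,
    dates: pd.DatetimeIndex,
    windows,
) -> np.ndarray:
    """Per-unit mean daily rainfall over the most recent complete austral
    winter (June-August) ending on or before each outcome window's end.

    Used as a ground-truth exposure when simulating a winter-rainfall effect.
    """
    intervals = []
    for w in windows:
        end = w.outcome_interval[1]
        year = end.year if end.month >= 8 else end.year - 1
        intervals.append((datetime.date(year, 6, 1), datetime.date(year, 8, 31)))
    return unit_window_rainfall(unit_daily, dates, intervals)


@dataclass
class PreparedDataset:
    """Zone x window model rows plus the metadata of their preparation.

    ``data`` columns: ``zone, window_id, y, pop, e, x``.  ``e`` may be NaN
    until expected counts are computed (see :func:`maupmtup.bym.compute_expected`).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        required = {"zone", "window_id", "y", "pop", "x"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"PreparedDataset missing columns {sorted(missing)}")
        if (df["y"] < 0).any() or (df["x"] < 0).any() or (df["pop"] < 0).any():
            raise ValueError("y, pop and x must be non-negative")
        if df.duplicated(["zone", "window_id"]).any():
            raise ValueError("each zone may appear only once per window")
        if "e" in df.columns and df["e"].notna().all():
            bad = (df["pop"] > 0) & (df["e"] <= 0)
            if bad.any():
                raise ValueError("expected counts must be positive where population > 0")


def aggregate_by_zonation(
    zonation,
    unit_events: np.ndarray,
    unit_pops: np.ndarray,
    unit_daily: np.ndarray,
    dates: pd.DatetimeIndex,
    windows,
    metadata: dict | None = None,
) -> PreparedDataset:
    """Aggregate unit-level data to the zones of ``zonation``.

    Zone events and populations are sums over comprised units; zone daily
    rainfall is the unweighted mean across comprised units, averaged over
    each window's rainfall interval to give ``x`` (mean daily mm).
    ``unit_events``/``unit_pops`` are ``(n_units, n_windows)`` aligned with
    ``windows``; ``unit_daily`` is ``(n_days, n_units)``.
    """
    labels = np.asarray(zonation.labels)
    n_units = len(labels)
    for name, arr in (("unit_events", unit_events), ("unit_pops", unit_pops)):
        if arr.shape != (n_units, len(windows)):
            raise ValueError(f"{name} must have shape (n_units, n_windows)")
    if unit_daily.shape[1] != n_units:
        raise ValueError("unit_daily must cover every unit in the zonation")
    if np.any(labels < 0):
        raise ValueError("zonation does not assign every unit")

    zones = np.unique(labels)
    member = {z: np.flatnonzero(labels == z) for z in zones}
    zone_daily = np.column_stack([unit_daily[:, member[z]].mean(axis=1) for z in zones])
    zone_x = unit_window_rainfall(zone_daily, dates, [w.rain_interval for w in windows])

    rows = []
    for zi, z in enumerate(zones):
        ev = unit_events[member[z]].sum(axis=0)
        pop = unit_pops[member[z]].sum(axis=0)
        for j, w in enumerate(windows):
            rows.append((int(z), w.window_id, int(ev[j]), float(pop[j]), float(zone_x[zi, j])))
    df = pd.DataFrame(rows, columns=["zone", "window_id", "y", "pop", "x"])
    df["e"] = np.nan
    return PreparedDataset(data=df, metadata=dict(metadata or {}))
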