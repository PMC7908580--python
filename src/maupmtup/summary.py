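"""Cross-zonation consistency classification and the arrangement grid.

Each temporal arrangement yields one rate-ratio estimate per zonation.  An
arrangement is *inconsistent* if any estimate's 95% credible interval
contains 1, or if any two estimates lie on opposite sides of 1; otherwise it
is *consistently positive* (all RRs above 1) or *consistently negative* (all
below 1).  An RR exactly equal to 1 necessarily has an interval containing 1
and is therefore inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bym import RateRatioEstimate
from .windows import MONTH_NAMES, WindowArrangement

CONSISTENTLY_NEGATIVE = "consistently_negative"
INCONSISTENT = "inconsistent"
CONSISTENTLY_POSITIVE = "consistently_positive"
LABELS = (CONSISTENTLY_NEGATIVE, INCONSISTENT, CONSISTENTLY_POSITIVE)


def classify_arrangement(estimates: Sequence[RateRatioEstimate]) -> str:
    """Consistency label for one arrangement's estimates across zonations."""
    if not estimates:
        raise ValueError("cannot classify an empty list of estimates")
    if any(est.contains_null for est in estimates):
        return INCONSISTENT
    signs = {est.rr > 1.0 for est in estimates}
    if len(signs) > 1:
        return INCONSISTENT
    return CONSISTENTLY_POSITIVE if signs.pop() else CONSISTENTLY_NEGATIVE


def mean_effect(estimates: Sequence[RateRatioEstimate]) -> float:
    """Arithmetic mean of the posterior-mean rate ratios."""
    if not estimates:
        raise ValueError("cannot average an empty list of estimates")
    return float(np.mean([est.rr for est in estimates]))


@dataclass(frozen=True)
class ArrangementSummary:
    """One arrangement's consistency label and mean effect across zonations."""

    arrangement: WindowArrangement
    gender: str
    label: str
    mean_rr: float
    n_estimates: int

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")


def summarize_arrangement(
    arrangement: WindowArrangement,
    gender: str,
    estimates: Sequence[RateRatioEstimate],
) -> ArrangementSummary:
    return ArrangementSummary(
        arrangement=arrangement,
        gender=gender,
        label=classify_arrangement(estimates),
        mean_rr=mean_effect(estimates),
        n_estimates=len(estimates),
    )


def build_grid(summaries: Iterable[ArrangementSummary]) -> pd.DataFrame:
    """Arrangement x lag grid: one row per (gender, endpoint, rain length, lag).

    Columns: ``gender, endpoint, rain_length, lag, label, mean_rr,
    n_estimates``.  Duplicate cells are rejected.
    """
    rows = []
    for s in summaries:
        a = s.arrangement
        rows.append(
            {
                "gender": s.gender,
                "endpoint": MONTH_NAMES[a.endpoint_month],
                "rain_length": a.rain_length_months,
                "lag": a.lag_months,
                "label": s.label,
                "mean_rr": s.mean_rr,
                "n_estimates": s.n_estimates,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if df.duplicated(["gender", "endpoint", "rain_length", "lag"]).any():
        dup = df[df.duplicated(["gender", "endpoint", "rain_length", "lag"])].iloc[0]
        raise ValueError(
            f"duplicate summary for cell ({dup['gender']}, {dup['endpoint']}, "
            f"{dup['rain_length']}, {dup['lag']})"
        )
    return df.sort_values(["gender", "endpoint", "rain_length", "lag"]).reset_index(drop=True)


def plot_grid(grid: pd.DataFrame, gender: str, ax=None):
    """Render one gender's grid as a coloured tile map (blue = consistently
    negative, green = inconsistent, red = consistently positive; shading by
    the absolute deviation of the mean RR from 1)."""
    import matplotlib.pyplot as plt
    from matplotlib import colors as mcolors

    sub = grid[grid["gender"] == gender]
    if sub.empty:
        raise ValueError(f"no summaries for gender {gender!r}")
    cols = sorted(
        sub[["endpoint", "rain_length"]].drop_duplicates().itertuples(index=False),
        key=lambda t: (t.endpoint, t.rain_length),
    )
    lags = sorted(sub["lag"].unique())
    base = {
        CONSISTENTLY_NEGATIVE: "tab:blue",
        INCONSISTENT: "tab:green",
        CONSISTENTLY_POSITIVE: "tab:red",
    }
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + len(cols), 1 + 0.6 * len(lags)))
    dev_max = max((sub["mean_rr"] - 1.0).abs().max(), 1e-6)
    for ci, col in enumerate(cols):
        for li, lag in enumerate(lags):
            cell = sub[
                (sub["endpoint"] == col.endpoint)
                & (sub["rain_length"] == col.rain_length)
                & (sub["lag"] == lag)
            ]
            if cell.empty:
                continue
            row = cell.iloc[0]
            shade = 0.3 + 0.7 * abs(row["mean_rr"] - 1.0) / dev_max
            rgba = mcolors.to_rgba(base[row["label"]], alpha=shade)
            ax.add_patch(plt.Rectangle((ci, li), 1, 1, facecolor=rgba, edgecolor="white"))
    ax.set_xlim(0, len(cols))
    ax.set_ylim(len(lags), 0)
    ax.set_xticks(np.arange(len(cols)) + 0.5)
    ax.set_xticklabels([f"{c.endpoint[:3]} {c.rain_length}" for c in cols], rotation=45)
    ax.set_yticks(np.arange(len(lags)) + 0.5)
    ax.set_yticklabels([str(l) for l in lags])
    ax.set_xlabel("outcome endpoint, rainfall length (months)")
    ax.set_ylabel("lag (months)")
    ax.set_title(f"Consistency of rainfall-outcome associations ({gender})")
    return ax
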