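"""Stochastic temperature-triggered bleaching events.

Bleaching is represented as a discrete loss of symbiont cells: whenever the
monthly SST exceeds the regional optimum ``T_opt`` by a margin that falls
inside one of the region's observed exceedance bands, the symbiont
abundance is multiplied by a retained fraction ``1 - rho/100``, where the
percent reduction ``rho`` is drawn uniformly from the band's observed
reduction range.  The band tables encode observed bleaching severity per
region:

======  ===============  ==================
Region  exceedance (C)   reduction (%)
======  ===============  ==================
GBR     2-4              10-95
GBR     >= 4             60-95
SEA     >= 1             25-95
CAR     1-3              15-95
CAR     3-6              35-95
CAR     >= 6             80-95
======  ===============  ==================

At most one event fires per calendar month (the forcing resolution); the
event is an instantaneous state reset applied between the monthly
integration segments.  Because the trigger depends only on the forcing,
event months and reductions can be pre-drawn for a whole run, which keeps
the bleaching randomness in a single seeded stream isolated from everything
else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BleachingBand",
    "BleachingEvent",
    "REGION_BANDS",
    "classify_exceedance",
    "apply_bleaching",
    "draw_monthly_reductions",
    "cumulative_bleaching_count",
    "events_to_frame",
]


@dataclass(frozen=True)
class BleachingBand:
    """One exceedance range and its observed symbiont-reduction range.

    ``exceedance_high`` may be ``inf`` for an open-ended top band.  Bands are
    half-open ``[low, high)`` so adjacent bands tile without overlap.
    """

    exceedance_low: float
    exceedance_high: float
    reduction_low: float
    reduction_high: float

    def __post_init__(self) -> None:
        if not self.exceedance_low < self.exceedance_high:
            raise ValueError("exceedance_low must be < exceedance_high")
        if not (0.0 <= self.reduction_low <= self.reduction_high <= 100.0):
            raise ValueError("reduction range must satisfy 0 <= low <= high <= 100")

    def contains(self, exceedance: float) -> bool:
        return self.exceedance_low <= exceedance < self.exceedance_high


@dataclass(frozen=True)
class BleachingEvent:
    """Record of one applied bleaching event."""

    time: int  # month index within the run
    exceedance: float  # T - T_opt in deg C
    band_index: int
    reduction_drawn: float  # percent of symbionts lost
    S_before: float
    S_after: float


#: Observed exceedance/reduction bands per region.
REGION_BANDS: dict[str, tuple[BleachingBand, ...]] = {
    "GBR": (
        BleachingBand(2.0, 4.0, 10.0, 95.0),
        BleachingBand(4.0, math.inf, 60.0, 95.0),
    ),
    "SEA": (BleachingBand(1.0, math.inf, 25.0, 95.0),),
    "CAR": (
        BleachingBand(1.0, 3.0, 15.0, 95.0),
        BleachingBand(3.0, 6.0, 35.0, 95.0),
        BleachingBand(6.0, math.inf, 80.0, 95.0),
    ),
}


def validate_bands(bands: Sequence[BleachingBand]) -> None:
    """Check ordering and non-overlap; raises ValueError on violation."""
    for prev, nxt in zip(bands, bands[1:]):
        if nxt.exceedance_low < prev.exceedance_high:
            raise ValueError(
                f"bleaching bands overlap or are unordered: "
                f"[{prev.exceedance_low}, {prev.exceedance_high}) then "
                f"[{nxt.exceedance_low}, {nxt.exceedance_high})"
            )


def classify_exceedance(
    T: float, T_opt: float, bands: Sequence[BleachingBand]
) -> Optional[int]:
    """Index of the band containing the exceedance ``T - T_opt``, else None.

    Returns None when the exceedance lies below the lowest band's lower
    edge (no bleaching) or in a gap between bands.
    """
    e = T - T_opt
    for i, band in enumerate(bands):
        if band.contains(e):
            return i
    return None


def apply_bleaching(
    S: float,
    band: BleachingBand,
    rng: np.random.Generator,
    *,
    time: int = -1,
    exceedance: float = float("nan"),
    band_index: int = -1,
) -> tuple[float, BleachingEvent]:
    """Draw a uniform reduction from ``band`` and apply it to ``S``.

    Returns the post-event abundance and the event record.  The reduction is
    a percent loss: a 95 % draw removes 95 % of the cells.
    """
    if S < 0:
        raise ValueError("symbiont abundance must be non-negative")
    rho = float(rng.uniform(band.reduction_low, band.reduction_high))
    S_after = (1.0 - rho / 100.0) * S
    event = BleachingEvent(time, exceedance, band_index, rho, S, S_after)
    return S_after, event


def draw_monthly_reductions(
    temperatures: np.ndarray,
    T_opt: float,
    bands: Sequence[BleachingBand],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, float, int, float]]]:
    """Pre-draw the retained-fraction multiplier for every month of a run.

    Returns ``(multipliers, stubs)`` where ``multipliers[m]`` is 1.0 for
    non-event months and ``1 - rho/100`` for event months, and each stub is
    ``(month_index, exceedance, band_index, reduction_pct)``.  Valid because
    the trigger and the drawn severity depend only on the forcing, never on
    the model state.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    mult = np.ones_like(temperatures)
    stubs: list[tuple[int, float, int, float]] = []
    for m, T in enumerate(temperatures):
        idx = classify_exceedance(float(T), T_opt, bands)
        if idx is None:
            continue
        band = bands[idx]
        rho = float(rng.uniform(band.reduction_low, band.reduction_high))
        mult[m] = 1.0 - rho / 100.0
        stubs.append((m, float(T) - T_opt, idx, rho))
    return mult, stubs


def cumulative_bleaching_count(
    series, T_opt: float, threshold: float = 2.0
) -> np.ndarray:
    """Cumulative count of months whose SST is at least ``T_opt + threshold``.

    This is the fixed-threshold bleaching counter used for scenario
    comparison plots (counting every month whose temperature exceeds the
    regional optimum by 2 deg C), independent of the banded stochastic
    event process.  ``series`` may be a TemperatureSeries or a plain array.
    """
    values = np.asarray(getattr(series, "values", series), dtype=float)
    return np.cumsum(values >= T_opt + threshold)


def events_to_frame(events: Sequence[BleachingEvent], series=None) -> pd.DataFrame:
    """Event log as a DataFrame (month_index, date, exceedance, band, ...)."""
    rows = []
    for ev in events:
        if series is not None:
            y, m = series.year_month(ev.time)
            date = f"{y:04d}-{m:02d}"
        else:
            date = ""
        rows.append(
            {
                "month_index": ev.time,
                "date": date,
                "exceedance_C": ev.exceedance,
                "band": ev.band_index,
                "reduction_pct": ev.reduction_drawn,
                "S_before": ev.S_before,
                "S_after": ev.S_after,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "month_index",
            "date",
            "exceedance_C",
            "band",
            "reduction_pct",
            "S_before",
            "S_after",
        ],
    )
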