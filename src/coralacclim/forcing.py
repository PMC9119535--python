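"""Monthly sea-surface-temperature forcing series.

The simulator runs at monthly resolution: every model experiment is driven
by a contiguous record of monthly mean SST for one region.  This module
provides the in-memory container (:class:`TemperatureSeries`), a CSV
reader/writer for the simple ``year,month,sst_c`` dialect, annual averaging
(used for the bleaching-free experiments, which remove the sub-annual
temperature fluctuations that trigger bleaching), concatenation of a
historical record with a scenario continuation, and a synthetic scenario
generator that emulates a warming SST record with a seasonal cycle and
month-to-month noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TemperatureSeries",
    "ScenarioSpec",
    "read_sst_series",
    "write_sst_series",
    "annual_average",
    "synthetic_forcing",
    "concat_series",
]


def _month_ordinal(year: int, month: int) -> int:
    """Absolute month counter (year*12 + zero-based month)."""
    return year * 12 + (month - 1)


@dataclass(frozen=True)
class TemperatureSeries:
    """A contiguous monthly SST record.

    Parameters
    ----------
    start
        ``(year, month)`` of the first value, month in 1..12.
    values
        Monthly mean SST in deg C, one value per month, no gaps.
    label
        Free-text description (region, scenario, provenance).
    """

    start: tuple[int, int]
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        y, m = self.start
        if not (1 <= m <= 12):
            raise ValueError(f"start month must be in 1..12, got {m}")
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("values must be a 1-d array with at least one month")
        if not np.all(np.isfinite(vals)):
            raise ValueError("temperature series contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def end(self) -> tuple[int, int]:
        """(year, month) of the last value."""
        return self.year_month(len(self) - 1)

    def year_month(self, index: int) -> tuple[int, int]:
        """Calendar (year, month) of the value at ``index``."""
        o = _month_ordinal(*self.start) + index
        return o // 12, o % 12 + 1

    def index_of(self, year: int, month: int = 1) -> int:
        """Index of calendar (year, month); may fall outside the record."""
        return _month_ordinal(year, month) - _month_ordinal(*self.start)

    @property
    def years(self) -> np.ndarray:
        """Calendar year of every month in the record."""
        o = _month_ordinal(*self.start) + np.arange(len(self))
        return o // 12

    @property
    def months(self) -> np.ndarray:
        """Calendar month (1..12) of every value."""
        o = _month_ordinal(*self.start) + np.arange(len(self))
        return o % 12 + 1

    def slice_years(self, first_year: int, last_year: int) -> "TemperatureSeries":
        """Sub-series covering the closed year range [first_year, last_year]."""
        i0 = max(self.index_of(first_year, 1), 0)
        i1 = min(self.index_of(last_year, 12), len(self) - 1)
        if i1 < i0:
            raise ValueError(
                f"series {self.start}..{self.end} does not cover years "
                f"{first_year}-{last_year}"
            )
        return TemperatureSeries(self.year_month(i0), self.values[i0 : i1 + 1], self.label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "month": self.months, "sst_c": self.values}
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for a synthetic warming scenario.

    ``target_rise`` is the scenario's headline warming: the mean of
    2081-2100 minus the mean of 1986-2005, the convention used for the RCP
    scenario ranges (0.3-1.7 deg C for RCP 2.6, 1.1-2.6 for RCP 4.5,
    2.6-4.8 for RCP 8.5).  The generated trend is rescaled so this window
    difference is met exactly when ``noise_sd`` is zero.
    """

    baseline_mean: float
    target_rise: float
    seasonal_amplitude: float = 1.25
    trend_shape: str = "linear"
    noise_sd: float = 0.35
    seed: int = 0
    span: tuple[int, int] = (1955, 2100)
    peak_month: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.trend_shape not in ("linear", "quadratic"):
            raise ValueError("trend_shape must be 'linear' or 'quadratic'")
        if self.span[1] < self.span[0]:
            raise ValueError("span must be (start_year, end_year) with start <= end")


def read_sst_series(path, label: str | None = None) -> TemperatureSeries:
    """Read a monthly SST record from CSV (columns ``year,month,sst_c``).

    Rows must be in chronological order.  Gaps of up to three months are
    filled by linear interpolation with a logged warning; longer gaps,
    duplicate or out-of-order dates, and unparseable rows are hard errors.
    """
    df = pd.read_csv(path)
    required = {"year", "month", "sst_c"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns year,month,sst_c; found {list(df.columns)}"
        )
    try:
        years = df["year"].astype(int).to_numpy()
        months = df["month"].astype(int).to_numpy()
        vals = df["sst_c"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: unparseable row ({exc})") from exc
    if np.any((months < 1) | (months > 12)):
        bad = int(np.argmax((months < 1) | (months > 12)))
        raise ValueError(f"{path}: row {bad}: month {months[bad]} outside 1..12")
    if not np.all(np.isfinite(vals)):
        bad = int(np.argmax(~np.isfinite(vals)))
        raise ValueError(f"{path}: row {bad}: non-finite sst_c")
    ords = years * 12 + (months - 1)
    steps = np.diff(ords)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0)) + 1
        raise ValueError(
            f"{path}: non-monotone dates at row {bad} "
            f"({years[bad]}-{months[bad]:02d})"
        )
    if np.any(steps > 4):
        bad = int(np.argmax(steps > 4)) + 1
        raise ValueError(
            f"{path}: gap of {steps[bad - 1] - 1} months (> 3) before row {bad} "
            f"({years[bad]}-{months[bad]:02d})"
        )
    n = int(ords[-1] - ords[0]) + 1
    full = np.full(n, np.nan)
    full[ords - ords[0]] = vals
    missing = np.isnan(full)
    if missing.any():
        logger.warning(
            "%s: filled %d missing month(s) by linear interpolation",
            path,
            int(missing.sum()),
        )
        idx = np.arange(n)
        full[missing] = np.interp(idx[missing], idx[~missing], full[~missing])
    start = (int(ords[0] // 12), int(ords[0] % 12 + 1))
    return TemperatureSeries(start, full, label if label is not None else str(path))


def write_sst_series(series: TemperatureSeries, path) -> None:
    """Write a series in the canonical ``year,month,sst_c`` CSV dialect."""
    series.to_frame().to_csv(path, index=False)


def annual_average(series: TemperatureSeries) -> TemperatureSeries:
    """Replace every month by its calendar-year mean (length preserved).

    Removes the within-year temperature fluctuations while keeping the
    long-term trend, which is how the bleaching-free model experiments are
    forced.  Partial boundary years are averaged over their available
    months (logged).
    """
    years = series.years
    vals = series.values.copy()
    out = np.empty_like(vals)
    for y in np.unique(years):
        sel = years == y
        if sel.sum() < 12:
            logger.info("annual_average: year %d has only %d months", y, int(sel.sum()))
        out[sel] = vals[sel].mean()
    return TemperatureSeries(series.start, out, f"{series.label} (annual mean)".strip())


def _window_mean(values: np.ndarray, series_years: np.ndarray, y0: int, y1: int) -> float:
    sel = (series_years >= y0) & (series_years <= y1)
    return float(values[sel].mean())


def synthetic_forcing(spec: ScenarioSpec) -> TemperatureSeries:
    """Generate a synthetic monthly SST scenario.

    The series is ``baseline_mean`` plus a monotone warming trend (linear or
    quadratic in time, affinely rescaled so that the 2081-2100 minus
    1986-2005 window difference equals ``target_rise`` exactly when the span
    covers both windows), a sinusoidal seasonal cycle peaking in
    ``peak_month``, and independent Gaussian monthly noise.
    """
    y0, y1 = spec.span
    n = (y1 - y0 + 1) * 12
    t = np.arange(n, dtype=float)
    if spec.trend_shape == "linear":
        raw = t
    else:
        raw = t**2
    series_years = y0 + (np.arange(n) // 12)
    if y0 <= 1986 and y1 >= 2100:
        base = _window_mean(raw, series_years, 1986, 2005)
        fut = _window_mean(raw, series_years, 2081, 2100)
        scale = spec.target_rise / (fut - base)
    else:
        # span does not cover the reference windows: spread the rise over the span
        scale = spec.target_rise / (raw[-1] - raw[0]) if n > 1 else 0.0
    trend = raw * scale
    trend -= trend[0]
    months = np.arange(n) % 12 + 1
    seasonal = spec.seasonal_amplitude * np.cos(
        2.0 * np.pi * (months - spec.peak_month) / 12.0
    )
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
    label = spec.label or f"synthetic rise={spec.target_rise:g}C"
    return TemperatureSeries((y0, 1), spec.baseline_mean + trend + seasonal + noise, label)


def concat_series(
    historical: TemperatureSeries, future: TemperatureSeries
) -> TemperatureSeries:
    """Join a historical record and its scenario continuation.

    The future series must start the month after the historical one ends,
    or overlap it; overlapping months are taken from the future series
    (logged), matching the convention of splicing an observed record with a
    model scenario.  A gap between the segments is a hard error.
    """
    h_end = _month_ordinal(*historical.end)
    f_start = _month_ordinal(*future.start)
    if f_start > h_end + 1:
        raise ValueError(
            f"gap between historical (ends {historical.end}) and future "
            f"(starts {future.start}) series"
        )
    keep = h_end + 1 - f_start  # number of overlapping months dropped from historical
    if keep > 0:
        logger.info("concat_series: future series overrides %d overlapping month(s)", keep)
        if keep >= len(historical):
            return replace(future, label=future.label)
        hist_vals = historical.values[:-keep]
    else:
        hist_vals = historical.values
    vals = np.concatenate([hist_vals, future.values])
    label = f"{historical.label} + {future.label}".strip(" +")
    return TemperatureSeries(historical.start, vals, label)
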