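"""Drought indices from daily rainfall.

Turns a daily precipitation record into the three environmental covariates
used throughout the package:

* **precipitation index** — the number of standard deviations the trailing
  30-day rainfall total lies above/below the mean total for the same
  calendar day across a set of reference years;
* **drought risk index** — the negated precipitation index, so that
  positive values mean drier-than-expected conditions;
* **expected rainfall** — the per-calendar-day mean z-score of the 30-day
  total across reference years, a smooth ±1-scale description of
  seasonality (≈ +1 in the wet season, ≈ −1 in the prolonged dry season).

Daily series are represented as :class:`pandas.Series` with a
``DatetimeIndex`` at daily frequency; missing days are ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "read_rainfall",
    "write_rainfall",
    "fill_missing",
    "rolling_30day_sum",
    "Climatology",
    "build_climatology",
    "drought_risk",
    "build_index_table",
    "write_index_table",
    "read_index_table",
]

#: length of the trailing accumulation window, in days
WINDOW = 30

#: cap (in SD units) applied when a calendar day's reference SD is zero
ZERO_SD_CAP = 5.0


def _validate_series(series: pd.Series) -> pd.Series:
    if len(series) == 0:
        raise ValueError("rainfall series is empty")
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("rainfall series must have a DatetimeIndex")
    if not series.index.is_monotonic_increasing or series.index.has_duplicates:
        raise ValueError("rainfall dates must be strictly increasing")
    # one record per calendar day across the span: absent days become NaN
    full = pd.date_range(series.index[0], series.index[-1], freq="D")
    series = series.reindex(full)
    if (series.dropna() < 0).any():
        raise ValueError("rainfall values must be non-negative")
    return series.astype(float)


def read_rainfall(path) -> pd.Series:
    """Read a two-column delimited file (date, rainfall_mm; empty = missing)."""
    df = pd.read_csv(path, parse_dates=["date"])
    s = pd.Series(df["rainfall_mm"].to_numpy(float), index=pd.DatetimeIndex(df["date"]))
    return _validate_series(s)


def write_rainfall(series: pd.Series, path) -> None:
    pd.DataFrame(
        {"date": series.index.strftime("%Y-%m-%d"), "rainfall_mm": series.to_numpy()}
    ).to_csv(path, index=False)


def fill_missing(series: pd.Series, half_window: int = 15) -> pd.Series:
    """Fill missing days from the surrounding month of observed days.

    A missing day is replaced by the mean rainfall over the ``half_window``
    days before and after it (30 neighbouring calendar days by default),
    provided at least half of those neighbours are themselves observed;
    otherwise it stays missing.  Observed days are never altered, and all
    fills are computed from the original (pre-fill) record.
    """
    series = _validate_series(series)
    values = series.to_numpy()
    out = values.copy()
    n = len(values)
    k = half_window
    missing_idx = np.flatnonzero(np.isnan(values))
    for i in missing_idx:
        lo, hi = max(0, i - k), min(n, i + k + 1)
        neighbours = np.concatenate([values[lo:i], values[i + 1 : hi]])
        observed = neighbours[~np.isnan(neighbours)]
        if len(observed) >= k:  # "at least half" of the 2k neighbour days
            out[i] = observed.mean()
    return pd.Series(out, index=series.index)


def rolling_30day_sum(series: pd.Series, window: int = WINDOW) -> pd.Series:
    """Trailing ``window``-day rainfall total ending on (and including) each day.

    The first ``window − 1`` days of the record, and any day whose window
    contains a missing value, are NaN.
    """
    series = _validate_series(series)
    return series.rolling(window, min_periods=window).sum()


@dataclass
class Climatology:
    """Per-calendar-day reference statistics of the 30-day rainfall total.

    ``per_day`` is indexed by (month, day) and carries the across-year mean,
    sample SD (n−1 denominator) and year count of the rolling totals for
    that calendar day over ``reference_years``.  ``expected_curve`` holds
    the expected-rainfall value for each (month, day): the mean across
    ``expected_reference_years`` of the globally standardized rolling
    total.  Feb 29 borrows Feb 28's statistics.
    """

    reference_years: tuple
    expected_reference_years: tuple
    per_day: pd.DataFrame
    global_mean: float
    global_sd: float
    expected_curve: pd.Series
    zero_sd_cap: float = ZERO_SD_CAP
    window: int = field(default=WINDOW)

    @staticmethod
    def _key(date) -> tuple:
        date = pd.Timestamp(date)
        if date.month == 2 and date.day == 29:
            return (2, 28)
        return (date.month, date.day)

    def day_stats(self, date) -> tuple:
        """(mean, sd, n_years) of the reference 30-day totals for this calendar day."""
        key = self._key(date)
        try:
            row = self.per_day.loc[key]
        except KeyError:
            raise KeyError(f"no reference statistics for calendar day {key}") from None
        if row["n_years"] < 2:
            raise ValueError(
                f"calendar day {key} has {int(row['n_years'])} reference value(s); need >= 2"
            )
        return float(row["mean"]), float(row["sd"]), int(row["n_years"])

    def precipitation_index(self, rolling_total: float, date) -> float:
        """SD units of ``rolling_total`` relative to this calendar day's reference."""
        if rolling_total is None or np.isnan(rolling_total):
            return np.nan
        mean, sd, _ = self.day_stats(date)
        if sd == 0.0:
            diff = rolling_total - mean
            return 0.0 if diff == 0.0 else float(np.sign(diff)) * self.zero_sd_cap
        return (rolling_total - mean) / sd

    def expected_rainfall_at(self, date) -> float:
        """Seasonal expected-rainfall value for the calendar day of ``date``."""
        key = self._key(date)
        try:
            return float(self.expected_curve.loc[key])
        except KeyError:
            raise KeyError(f"calendar day {key} outside known calendar") from None


def build_climatology(
    series: pd.Series,
    reference_years,
    expected_reference_years=None,
    window: int = WINDOW,
    zero_sd_cap: float = ZERO_SD_CAP,
) -> Climatology:
    """Build per-calendar-day reference statistics from a daily series.

    ``reference_years`` feed the per-day mean/SD used by the precipitation
    index; ``expected_reference_years`` (default: same set) feed the
    expected-rainfall curve.  The global mean/SD standardizing that curve
    are computed over all rolling totals in the expected-reference period.
    """
    if expected_reference_years is None:
        expected_reference_years = reference_years
    reference_years = tuple(sorted(set(int(y) for y in reference_years)))
    expected_reference_years = tuple(sorted(set(int(y) for y in expected_reference_years)))
    if len(reference_years) < 2:
        raise ValueError("need at least 2 reference years")

    totals = rolling_30day_sum(series, window=window)
    df = pd.DataFrame(
        {
            "total": totals.to_numpy(),
            "year": totals.index.year,
            "month": totals.index.month,
            "day": totals.index.day,
        }
    ).dropna(subset=["total"])
    # leap day borrows Feb 28
    df = df[~((df["month"] == 2) & (df["day"] == 29))]

    ref = df[df["year"].isin(reference_years)]
    per_day = (
        ref.groupby(["month", "day"])["total"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n_years="count")
        .astype({"n_years": int})
    )

    exp_ref = df[df["year"].isin(expected_reference_years)]
    if len(exp_ref) == 0:
        raise ValueError("no rolling totals fall in the expected-rainfall reference years")
    global_mean = float(exp_ref["total"].mean())
    global_sd = float(exp_ref["total"].std(ddof=1))
    if not global_sd > 0:
        # constant rainfall in every reference year: the curve is identically 0
        z = pd.Series(0.0, index=exp_ref.set_index(["month", "day"]).index.unique())
        expected_curve = z.sort_index()
    else:
        exp_ref = exp_ref.assign(z=(exp_ref["total"] - global_mean) / global_sd)
        expected_curve = exp_ref.groupby(["month", "day"])["z"].mean().sort_index()

    return Climatology(
        reference_years=reference_years,
        expected_reference_years=expected_reference_years,
        per_day=per_day,
        global_mean=global_mean,
        global_sd=global_sd if global_sd > 0 else 0.0,
        expected_curve=expected_curve,
        zero_sd_cap=zero_sd_cap,
        window=window,
    )


def drought_risk(precipitation_index):
    """Invert the precipitation index: positive values = higher drought risk.

    Exact negation; NaN propagates. Accepts scalars or arrays/Series.
    """
    return -precipitation_index


def build_index_table(series: pd.Series, climatology: Climatology) -> pd.DataFrame:
    """Per-day table of rolling total, precipitation index, drought risk, expected rainfall."""
    series = _validate_series(series)
    totals = rolling_30day_sum(series, window=climatology.window)
    pidx = np.array(
        [climatology.precipitation_index(t, d) for t, d in zip(totals.to_numpy(), totals.index)]
    )
    expected = np.array([climatology.expected_rainfall_at(d) for d in totals.index])
    return pd.DataFrame(
        {
            "date": totals.index,
            "rolling_30day_total": totals.to_numpy(),
            "precipitation_index": pidx,
            "drought_risk": drought_risk(pidx),
            "expected_rainfall": expected,
        }
    )


def write_index_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_index_table(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])
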