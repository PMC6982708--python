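"""Raw series to regression-ready table.

Hourly averaging, wind-direction decomposition, log transforms, and the
season x daytype classification (thermal seasons from a smoothed daily
temperature curve; workday/weekend split with public holidays).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import (
    ALL_CLASSES,
    ClassLabel,
    ConfigError,
    TimeTable,
    VariableSpec,
)

logger = logging.getLogger("aqproxy.preprocessing")

WINTER_MAX_C = 0.0   # smoothed daily mean below this -> winter
SUMMER_MIN_C = 10.0  # smoothed daily mean above this -> summer


@dataclass
class SeasonBoundaries:
    """Thermal-season change points covering the study period.

    ``segments`` is an ordered list of ``(start_date, season)`` pairs;
    each segment runs until the next start (the last to the period end).
    """

    segments: list  # [(datetime.date, season)]
    period: tuple   # (first_date, last_date) covered
    smoothing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (_, a), (_, b) in zip(self.segments, self.segments[1:]):
            if a == b:
                raise ValueError("consecutive segments must differ in season")

    def season_of(self, dates) -> pd.Series:
        """Vectorized season lookup for a DatetimeIndex or date sequence."""
        idx = pd.DatetimeIndex(pd.to_datetime(list(dates)))
        starts = pd.DatetimeIndex([pd.Timestamp(d) for d, _ in self.segments])
        labels = np.array([s for _, s in self.segments], dtype=object)
        pos = starts.searchsorted(idx.normalize(), side="right") - 1
        if (pos < 0).any() or (idx.normalize() > pd.Timestamp(self.period[1])).any():
            raise ConfigError("timestamp outside season coverage")
        return pd.Series(labels[pos], index=idx)

    def days_per_season(self) -> dict:
        counts = {}
        days = pd.date_range(self.period[0], self.period[1], freq="D")
        seasons = self.season_of(days)
        for s, n in seasons.value_counts().items():
            counts[s] = int(n)
        return counts


def resample_hourly(table: TimeTable) -> TimeTable:
    """Average sub-hourly samples onto the clock hour.

    The value for hour ``h`` is the arithmetic mean of the non-missing
    samples in ``[h, h+1)``; an hour with no valid sample stays missing.
    Idempotent on already-hourly tables.
    """
    if len(table) == 0:
        return table.copy()
    hourly = table.frame.resample("1h").mean()
    return TimeTable(hourly, tz_label=table.tz_label, meta=dict(table.meta))


def decompose_wind(direction_deg: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Resolve a wind-direction angle into north-south / east-west components.

    Meteorological convention: degrees clockwise from north, so
    ``wd_n = cos(theta)`` and ``wd_e = sin(theta)``. Missing propagates;
    values outside [0, 360) are reduced modulo 360 with a warning.
    """
    vals = direction_deg.astype(float)
    out_of_range = ((vals < 0) | (vals >= 360)) & vals.notna()
    if out_of_range.any():
        logger.warning(
            "%d wind-direction values outside [0, 360) reduced modulo 360",
            int(out_of_range.sum()),
        )
        vals = vals.mod(360)
    rad = np.deg2rad(vals)
    return np.cos(rad), np.sin(rad)


def apply_transforms(table: TimeTable, specs: list[VariableSpec]) -> TimeTable:
    """Return the table on the fitting scale.

    Log-transform variables are replaced by their natural log (non-positive
    values become missing, count logged); wind-direction variables are
    replaced by ``<name>_N`` / ``<name>_E`` component columns; identity
    variables pass through untouched.
    """
    frame = table.frame.copy()
    spec_map = {s.name: s for s in specs}
    nonpos_total = 0
    for name in list(frame.columns):
        spec = spec_map.get(name)
        if spec is None or spec.transform == "identity":
            continue
        if spec.transform == "log":
            col = frame[name]
            nonpos = (col <= 0) & col.notna()
            nonpos_total += int(nonpos.sum())
            frame[name] = np.log(col.where(~nonpos))
        elif spec.transform == "wind_direction":
            wd_n, wd_e = decompose_wind(frame[name])
            frame = frame.drop(columns=[name])
            frame[f"{name}_N"] = wd_n
            frame[f"{name}_E"] = wd_e
    if nonpos_total:
        logger.info("%d non-positive values set missing under log", nonpos_total)
    out = TimeTable(frame, tz_label=table.tz_label, meta=dict(table.meta))
    out.meta["nonpositive_under_log"] = nonpos_total
    return out


def transformed_candidate_names(specs: list[VariableSpec]) -> list[str]:
    """Candidate column names after apply_transforms (wind split in two)."""
    names = []
    for s in specs:
        if s.role != "candidate":
            continue
        if s.transform == "wind_direction":
            names.extend([f"{s.name}_N", f"{s.name}_E"])
        else:
            names.append(s.name)
    return names


def fit_thermal_seasons(
    daily_temp: pd.Series, span_days: int = 60
) -> SeasonBoundaries:
    """Label every study day with a thermal season from smoothed daily means.

    A lowess curve (local linear smoothing, window ``span_days``) is fitted
    to the daily mean temperature; days where the curve is below 0 degC are
    winter, above 10 degC summer, and days in between are spring on a rising
    curve and autumn on a falling one.
    """
    temp = daily_temp.dropna()
    if temp.empty:
        raise ConfigError("all-missing temperature: season classification impossible")
    if len(temp) < 60:
        raise ConfigError("need >= 60 daily temperature values to fit seasons")
    first = daily_temp.index.min().date()
    last = daily_temp.index.max().date()
    days = pd.date_range(first, last, freq="D")
    x = (temp.index - pd.Timestamp(first)).days.to_numpy(dtype=float)
    frac = min(1.0, span_days / max(len(temp), 1))
    xgrid = (days - pd.Timestamp(first)).days.to_numpy(dtype=float)
    smooth = lowess(temp.to_numpy(), x, frac=frac, xvals=xgrid)
    slope = np.gradient(smooth, xgrid)

    labels = np.where(
        smooth < WINTER_MAX_C,
        "winter",
        np.where(
            smooth > SUMMER_MIN_C,
            "summer",
            np.where(slope >= 0, "spring", "autumn"),
        ),
    )
    segments = [(days[0].date(), labels[0])]
    for d, lab in zip(days[1:], labels[1:]):
        if lab != segments[-1][1]:
            segments.append((d.date(), lab))
    return SeasonBoundaries(
        segments=segments,
        period=(first, last),
        smoothing={"method": "lowess", "span_days": span_days},
    )


def classify_daytype(dates, holidays: frozenset) -> pd.Series:
    """Label calendar days: Saturday/Sunday/public holiday -> weekend."""
    idx = pd.DatetimeIndex(pd.to_datetime(list(dates)))
    is_weekend = idx.weekday >= 5
    is_holiday = np.array([d.date() in holidays for d in idx])
    labels = np.where(is_weekend | is_holiday, "weekend", "workday")
    return pd.Series(labels, index=idx)


def assign_classes(
    table: TimeTable, seasons: SeasonBoundaries, holidays: frozenset
) -> pd.Series:
    """Map every timestamp to its (season, daytype) class.

    Returns a Series of :class:`ClassLabel` aligned to the table index;
    per-class row counts are logged.
    """
    idx = table.timestamps
    season = seasons.season_of(idx).to_numpy()
    daytype = classify_daytype(idx, holidays).to_numpy()
    labels = pd.Series(
        [ClassLabel(s, d) for s, d in zip(season, daytype)], index=idx
    )
    counts = labels.value_counts()
    for cls in ALL_CLASSES:
        logger.info("class %s: %d rows", cls, int(counts.get(cls, 0)))
    return labels
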