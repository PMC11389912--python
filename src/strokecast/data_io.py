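"""Reading, writing and validation of the CSV/JSON artifacts.

Two in-memory containers are used throughout the package:

* a *daily count series*: :class:`pandas.Series` named ``"count"`` on a
  complete daily :class:`~pandas.DatetimeIndex` (missing days are ``NaN``
  unless a fill policy says otherwise);
* a *meteorological table*: :class:`pandas.DataFrame` on the same kind of
  calendar with the eleven columns in :data:`METEO_VARS` — daily minimum /
  maximum / mean temperature and temperature amplitude (°C), mean relative
  humidity (%), mean water-vapour pressure (hPa), wind speed (m/s),
  precipitation (mm), and the three thermal-comfort indices ETV, WCI, DI.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

#: The eleven meteorological / thermal-comfort variables, in canonical order.
METEO_VARS = [
    "t_min", "t_max", "t_mean", "t_ampl",
    "humidity", "pressure", "wind", "precipitation",
    "ETV", "WCI", "DI",
]

#: Variables measured directly (the comfort indices can be derived).
BASE_METEO_VARS = METEO_VARS[:8]

#: Core columns of a forecast-log CSV.
FORECAST_LOG_COLUMNS = ["date", "truth", "score_glm", "score_rfts", "score_croston"]


class ValidationError(ValueError):
    """An input file or table violates a domain invariant."""


def _full_calendar(index: pd.DatetimeIndex) -> pd.DatetimeIndex:
    return pd.date_range(index.min(), index.max(), freq="D")


def validate_counts(series: pd.Series) -> pd.Series:
    """Check count-series invariants; return the series unchanged.

    Counts must be non-negative and integral where present; the index must
    be strictly increasing daily dates without duplicates.
    """
    if series.index.has_duplicates:
        dup = series.index[series.index.duplicated()][0]
        raise ValidationError(f"duplicate date in count series: {dup.date()}")
    if not series.index.is_monotonic_increasing:
        raise ValidationError("count series dates are not increasing")
    values = series.to_numpy(dtype=float)
    present = ~np.isnan(values)
    if np.any(values[present] < 0):
        raise ValidationError("negative counts are not allowed")
    if np.any(values[present] != np.round(values[present])):
        raise ValidationError("counts must be integers")
    return series


def read_counts(path: str | Path, fill_policy: str = "na") -> pd.Series:
    """Read a ``date,count`` CSV into a daily count series on a full calendar.

    Parameters
    ----------
    path
        CSV file with header columns ``date`` (ISO-8601) and ``count``.
    fill_policy
        How to treat days absent from the file within the covered span:
        ``"na"`` keeps them as missing, ``"zero"`` inserts 0,
        ``"error"`` refuses gaps.
    """
    if fill_policy not in ("na", "zero", "error"):
        raise ValueError(f"unknown fill_policy: {fill_policy!r}")
    frame = pd.read_csv(path)
    if "date" not in frame.columns or "count" not in frame.columns:
        raise ValidationError("counts CSV needs 'date' and 'count' columns")
    idx = pd.DatetimeIndex(pd.to_datetime(frame["date"], format="ISO8601"))
    series = pd.Series(frame["count"].to_numpy(dtype=float), index=idx, name="count")
    if series.index.has_duplicates:
        validate_counts(series)  # raises with the duplicate date
    series = series.sort_index()
    validate_counts(series)
    full = _full_calendar(series.index)
    n_missing = len(full) - series.notna().sum()
    if fill_policy == "error" and n_missing > 0:
        raise ValidationError(f"{n_missing} day(s) missing from count series")
    series = series.reindex(full)
    if fill_policy == "zero":
        series = series.fillna(0.0)
    series.index.name = "date"
    series.attrs["n_missing"] = int(n_missing)
    return series


def validate_meteo(table: pd.DataFrame) -> pd.DataFrame:
    """Check meteorological invariants; return the table unchanged."""
    hum = table["humidity"].to_numpy(dtype=float)
    present = ~np.isnan(hum)
    if np.any((hum[present] < 0) | (hum[present] > 100)):
        raise ValidationError("humidity outside [0, 100]")
    t = table[["t_min", "t_mean", "t_max"]].to_numpy(dtype=float)
    rows = ~np.isnan(t).any(axis=1)
    if np.any(t[rows, 0] > t[rows, 1] + 1e-9) or np.any(t[rows, 1] > t[rows, 2] + 1e-9):
        raise ValidationError("temperature ordering t_min <= t_mean <= t_max violated")
    if "t_ampl" in table:
        a = table["t_ampl"].to_numpy(dtype=float)
        ok = rows & ~np.isnan(a)
        if np.any(np.abs(a[ok] - (t[ok, 2] - t[ok, 0])) > 0.1):
            raise ValidationError("t_ampl inconsistent with t_max - t_min")
    for col in ("wind", "precipitation", "pressure"):
        v = table[col].to_numpy(dtype=float)
        if np.any(v[~np.isnan(v)] < 0):
            raise ValidationError(f"negative {col}")
    return table


def read_meteo(path: str | Path, ffill_limit: int = 3) -> pd.DataFrame:
    """Read a meteorological CSV, impute short gaps and derive missing columns.

    The file must carry ``date`` plus the eight base variables; ``t_ampl``
    is imputed as ``t_max - t_min`` when absent and the comfort indices
    ETV/WCI/DI are computed from their standard formulas when absent.
    Interior missing values are forward-filled up to ``ffill_limit`` days;
    longer gaps are left missing and reported with a warning.
    """
    from .synthetic import compute_indices

    frame = pd.read_csv(path)
    if "date" not in frame.columns:
        raise ValidationError("meteo CSV needs a 'date' column")
    idx = pd.DatetimeIndex(pd.to_datetime(frame.pop("date"), format="ISO8601"))
    if idx.has_duplicates:
        raise ValidationError("duplicate date in meteo table")
    known = [c for c in frame.columns if c in METEO_VARS]
    unknown = [c for c in frame.columns if c not in METEO_VARS]
    if unknown:
        warnings.warn(f"ignoring unknown meteo columns: {unknown}")
    table = frame[known].astype(float).set_axis(idx).sort_index()
    required = [c for c in BASE_METEO_VARS if c != "t_ampl"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"meteo CSV lacks required columns: {missing}")
    if "t_ampl" not in table.columns:
        table["t_ampl"] = table["t_max"] - table["t_min"]
    table = table.reindex(_full_calendar(table.index))
    filled = table.ffill(limit=ffill_limit)
    still = filled.isna() & table.notna().cummax()  # gaps after the first record
    table = filled
    if still.to_numpy().any():
        cols = list(table.columns[still.any(axis=0)])
        warnings.warn(f"meteo gaps longer than {ffill_limit} days remain in {cols}")
    if any(c not in table.columns for c in ("ETV", "WCI", "DI")):
        table = compute_indices(table)
    table = table[METEO_VARS]
    table.index.name = "date"
    return validate_meteo(table)


def write_counts(series: pd.Series, path: str | Path) -> None:
    frame = pd.DataFrame({"date": series.index.strftime("%Y-%m-%d"), "count": series.to_numpy()})
    frame.to_csv(path, index=False)


def write_meteo(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.insert(0, "date", table.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False)


def write_forecast_log(log: pd.DataFrame, path: str | Path) -> None:
    """Write a forecast log (one row per forecast day) to CSV."""
    out = log.copy()
    if isinstance(out.index, pd.DatetimeIndex):
        out = out.reset_index(names="date")
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_forecast_log(path: str | Path) -> pd.DataFrame:
    log = pd.read_csv(path)
    if "date" not in log.columns:
        raise ValidationError("forecast log needs a 'date' column")
    log["date"] = pd.to_datetime(log["date"], format="ISO8601")
    return log.set_index("date")


def write_report(report: dict, path: str | Path) -> None:
    """Write an evaluation report as JSON (lossless round trip)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
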