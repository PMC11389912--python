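"""Lagged design matrices for the extreme-day models.

The model regresses the binary extreme indicator at day t on its own lags
1–3, the eleven meteorological variables at lags 1–3 (optionally 7-day
rolling means), and calendar terms: day-of-week (categorical), ISO
week-of-year (numeric), month (categorical), year (categorical).
Categoricals are treatment-coded with the first level as reference, so the
design is full column rank on generic data (exactly collinear columns such
as a lagged temperature amplitude alongside the lagged min/max pair are
handled downstream by the fitters' aliasing guard).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import METEO_VARS
from .extremes import rolling_mean

__all__ = ["LagDesign", "calendar_terms", "make_lag_design", "SequentialDesign"]


@dataclass
class LagDesign:
    """A model-ready design: response, predictor matrix and term blocks.

    ``terms`` maps a term name (e.g. ``"t_max_lag2"`` or ``"month"``) to
    the column indices it occupies in ``X``; categorical terms occupy a
    block of dummy columns and are added or dropped as a unit.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    terms: dict[str, list[int]]
    index: pd.DatetimeIndex
    n_dropped: int = 0  # rows lost to incomplete lags / warm-up

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.columns, index=self.index)
        frame.insert(0, "ext", self.y)
        return frame

    def subset(self, keep_terms: list[str]) -> "LagDesign":
        cols = [i for t in keep_terms for i in self.terms[t]]
        terms, pos = {}, 0
        for t in keep_terms:
            terms[t] = list(range(pos, pos + len(self.terms[t])))
            pos += len(self.terms[t])
        return LagDesign(self.X[:, cols], self.y, [self.columns[i] for i in cols],
                         terms, self.index, self.n_dropped)


def calendar_terms(dates: pd.DatetimeIndex) -> pd.DataFrame:
    """Day-of-week, ISO week, month and year labels for each date."""
    iso = dates.isocalendar()
    return pd.DataFrame(
        {
            "day": dates.day_name(),
            "week": iso["week"].to_numpy(dtype=int),
            "month": dates.month,
            "year": dates.year,
        },
        index=dates,
    )


_DOW = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday"]


def _calendar_matrix(dates: pd.DatetimeIndex) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Treatment-coded calendar block (reference level dropped)."""
    cal = calendar_terms(dates)
    cols: list[np.ndarray] = []
    names: list[str] = []
    terms: dict[str, list[int]] = {}

    def add(term: str, block: list[tuple[str, np.ndarray]]):
        start = len(names)
        for name, col in block:
            names.append(name)
            cols.append(col)
        terms[term] = list(range(start, len(names)))

    add("day", [(f"day_{d}", (cal["day"] == d).to_numpy(dtype=float)) for d in _DOW[1:]])
    add("week", [("week", cal["week"].to_numpy(dtype=float))])
    add("month", [(f"month_{m}", (cal["month"] == m).to_numpy(dtype=float)) for m in range(2, 13)])
    years = sorted(cal["year"].unique())
    add("year", [(f"year_{y}", (cal["year"] == y).to_numpy(dtype=float)) for y in years[1:]])
    return np.column_stack(cols), names, terms


class SequentialDesign:
    """Precomputed static design blocks for fast expanding-window refits.

    The meteorological lag columns and calendar encoding depend only on
    the calendar, so they are built once; per forecast origin only the
    extreme-indicator lag columns and the response change. Row t of the
    static matrix holds the predictors needed to *score* day t (they use
    information up to day t-1 only).
    """

    def __init__(self, meteo: pd.DataFrame, *, meteo_lags=(1, 2, 3),
                 ext_lags=(1, 2, 3), smooth_meteo: bool = True, window: int = 7,
                 variables: list[str] | None = None, calendar: bool = True):
        self.ext_lags = tuple(ext_lags)
        self.meteo_lags = tuple(meteo_lags)
        self.dates = meteo.index
        variables = list(variables or METEO_VARS)
        n = len(meteo)
        cols, names = [], []
        terms: dict[str, list[int]] = {}
        names.append("Intercept")
        cols.append(np.ones(n))
        terms["Intercept"] = [0]
        for lag in self.ext_lags:  # placeholders; filled per origin
            names.append(f"ext_lag{lag}")
            cols.append(np.full(n, np.nan))
            terms[f"ext_lag{lag}"] = [len(names) - 1]
        for var in variables:
            base = meteo[var]
            if smooth_meteo:
                base = rolling_mean(base, window=window)
            arr = base.to_numpy(dtype=float)
            for lag in self.meteo_lags:
                shifted = np.full(n, np.nan)
                shifted[lag:] = arr[: n - lag]
                names.append(f"{var}_lag{lag}")
                cols.append(shifted)
                terms[f"{var}_lag{lag}"] = [len(names) - 1]
        X = np.column_stack(cols)
        if calendar:
            calX, calnames, calterms = _calendar_matrix(self.dates)
            offset = X.shape[1]
            X = np.hstack([X, calX])
            names += calnames
            terms.update({t: [offset + i for i in ix] for t, ix in calterms.items()})
        self.X = X
        self.columns = names
        self.terms = terms
        self._ext_cols = [terms[f"ext_lag{lag}"][0] for lag in self.ext_lags]
        self._static_ok = ~np.isnan(np.delete(X, self._ext_cols, axis=1)).any(axis=1)

    def fill_ext(self, ext_values: np.ndarray) -> np.ndarray:
        """Return a copy of X with the extreme-lag columns filled.

        ``ext_values`` is the 0/1/NaN extreme series aligned to the
        calendar (it may be shorter; the tail is treated as unknown).
        """
        n = len(self.dates)
        e = np.full(n, np.nan)
        e[: len(ext_values)] = ext_values
        X = self.X.copy()
        for lag, col in zip(self.ext_lags, self._ext_cols):
            X[lag:, col] = e[: n - lag]
        return X

    def design_rows(self, ext_values: np.ndarray, upto: int | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Complete training rows (X, y) for targets within ``ext_values``.

        Returns ``(X, y, row_positions)`` restricted to days whose
        response and all predictors are present, using only the first
        ``upto`` days (default: all of ``ext_values``).
        """
        m = len(ext_values) if upto is None else min(upto, len(ext_values))
        Xfull = self.fill_ext(ext_values)
        y = np.full(len(self.dates), np.nan)
        y[:m] = ext_values[:m]
        ok = self._static_ok & ~np.isnan(y)
        ok &= ~np.isnan(Xfull[:, self._ext_cols]).any(axis=1)
        rows = np.flatnonzero(ok)
        return Xfull[rows], y[rows], rows

    def scoring_row(self, ext_values: np.ndarray, t: int) -> np.ndarray | None:
        """Feature row for day ``t`` (0-based) or None if incomplete."""
        X = self.fill_ext(ext_values)
        row = X[t]
        return None if np.isnan(row).any() else row


def make_lag_design(ext: pd.Series | pd.DataFrame, meteo: pd.DataFrame, *,
                    ext_lags=(1, 2, 3), meteo_lags=(1, 2, 3),
                    smooth_meteo: bool = True, window: int = 7,
                    calendar: bool = True) -> LagDesign:
    """Build the lagged design matrix for the extreme-day model.

    Parameters
    ----------
    ext
        The binary extreme series (or the frame from
        :func:`strokecast.extremes.build_ext`, whose ``ext`` column is
        used); warm-up days are missing and drop out of the design.
    meteo
        Meteorological table on a calendar overlapping ``ext``'s.
    smooth_meteo
        Replace each meteorological variable by its trailing 7-day rolling
        mean before lagging (the smoothed-series analysis convention).

    Rows with any missing predictor or response are dropped; their number
    is recorded as ``n_dropped``.
    """
    if isinstance(ext, pd.DataFrame):
        ext = ext["ext"]
    common = ext.index.intersection(meteo.index)
    if len(common) == 0:
        raise ValueError("ext and meteo calendars are disjoint")
    ext = ext.reindex(common)
    sd = SequentialDesign(meteo.loc[common], meteo_lags=meteo_lags, ext_lags=ext_lags,
                          smooth_meteo=smooth_meteo, window=window, calendar=calendar)
    X, y, rows = sd.design_rows(ext.to_numpy(dtype=float))
    return LagDesign(X, y, sd.columns, sd.terms, common[rows],
                     n_dropped=len(common) - len(rows))
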