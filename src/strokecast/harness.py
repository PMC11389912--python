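"""Sequential one-step-ahead forecasting study.

From a start day (default 500, counted 1-based from the series start)
forward, each forecast origin t:

1. takes the binary extreme series up to t−1 as the forecasters' history;
2. refits the logistic model and the random forest on the lagged design
   over that history (on their refit schedules) and scores the day-t
   feature row — training rows and feature lags only ever use days ≤ t−1;
3. advances Croston's recursion along the extreme history and records its
   current rate;
4. compares every score against the ground truth Ext_t.

Two constructions of the extreme series are supported. The default,
``ext_mode="retrospective"``, builds it once from the full count series:
the target being forecast is then the retrospectively defined extreme
indicator, and the one-step-ahead discipline applies to model fitting and
to the lagged predictors. ``ext_mode="sequential"`` instead rebuilds the
whole construction (rolling sum → spline → past-percentile threshold) on
the counts truncated at each origin, so even the spline never sees the
future; its boundary behavior makes the resulting ground truth much
rarer than the nominal 10 % (a smoothing spline has high leverage at the
last point, shrinking the day-t residual toward zero), which is why it is
not the default. See the methods documentation for the full argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .extremes import build_ext
from .features import SequentialDesign
from .forecasters import croston_forecast, fit_forest, fit_logistic

__all__ = ["run_sequential"]

DEFAULT_REFIT = {"glm": 1, "rfts": 7, "croston": 1}


def _forest_seed(seed: int, t: int) -> int:
    return int((np.uint64(seed) * np.uint64(1000003) + np.uint64(t)) % np.uint64(2**31 - 1))


def run_sequential(counts: pd.Series, meteo: pd.DataFrame, *, start: int = 500,
                   methods: tuple[str, ...] = ("glm", "rfts", "croston"),
                   seed: int = 0, refit_every: dict[str, int] | None = None,
                   ext_mode: str = "retrospective", alpha: float = 0.5,
                   window: int = 7, q: float = 0.90, min_history: int = 100,
                   smoothing: str | float = "gcv", smooth_meteo: bool = True,
                   n_trees: int = 500, forest_bootstrap: str = "iid",
                   block_length: int = 10, progress: bool = False) -> pd.DataFrame:
    """Run the expanding-window forecasting study.

    Returns a forecast log indexed by date with the ground truth, one
    score column per method, the training size, per-method refit flags
    and the spline penalty in effect that day. Days where a model cannot
    produce a score (e.g. a single-class training response) are recorded
    as missing, never dropped.
    """
    n = len(counts)
    if n <= start + 1:
        raise ValueError(f"series length {n} too short for start={start}")
    unknown = set(methods) - {"glm", "rfts", "croston"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if ext_mode not in ("retrospective", "sequential"):
        raise ValueError(f"unknown ext_mode {ext_mode!r}")
    refit = dict(DEFAULT_REFIT)
    refit.update(refit_every or {})

    meteo = meteo.reindex(counts.index)
    builder = SequentialDesign(meteo, smooth_meteo=smooth_meteo, window=window)

    ext_kw = dict(window=window, q=q, min_history=min_history, smoothing=smoothing)
    if ext_mode == "retrospective":
        full = build_ext(counts, **ext_kw)
        ext_all = full["ext"].to_numpy(dtype=float)
        lam0 = full.attrs.get("lam", np.nan)
    else:
        prev = build_ext(counts, upto=start - 1, **ext_kw)

    records = []
    glm_model = None
    rf_model = None
    last_n_train = np.nan
    for t in range(start, n + 1):  # 1-based forecast origins
        step = t - start
        if ext_mode == "retrospective":
            ext_hist = ext_all[: t - 1]
            truth = ext_all[t - 1]
            lam = lam0
        else:
            ext_hist = prev["ext"].to_numpy(dtype=float)
            lam = prev.attrs.get("lam", np.nan)
        rec: dict = {"date": counts.index[t - 1], "lam": lam}
        row = builder.scoring_row(ext_hist, t - 1)

        need_design = ("glm" in methods and (step % refit["glm"] == 0 or glm_model is None)) or (
            "rfts" in methods and (step % refit["rfts"] == 0 or rf_model is None))
        X = y = None
        if need_design:
            X, y, _ = builder.design_rows(ext_hist)
            last_n_train = len(y)
        rec["n_train"] = last_n_train

        if "glm" in methods:
            refit_now = step % refit["glm"] == 0 or glm_model is None
            if refit_now and y is not None and len(np.unique(y)) == 2:
                # cold start on every refit: with quasi-separated calendar
                # cells (a level with no extreme events) the MLE is at
                # infinity, and a warm-start chain would keep drifting
                # along it, making logged scores irreproducible from a
                # single fit on the same truncated data. Aliasing is also
                # re-detected each time (dummies gain support as the
                # window grows).
                glm_model = fit_logistic(X, y)
            rec["refit_glm"] = bool(refit_now)
            rec["score_glm"] = (
                float(glm_model.predict(row)[0])
                if glm_model is not None and row is not None else np.nan
            )
        if "rfts" in methods:
            refit_now = step % refit["rfts"] == 0 or rf_model is None
            if refit_now and y is not None:
                rf_model = fit_forest(X, y, n_trees=n_trees,
                                      seed=_forest_seed(seed, t),
                                      bootstrap=forest_bootstrap,
                                      block_length=block_length)
            rec["refit_rfts"] = bool(refit_now)
            rec["score_rfts"] = (
                float(rf_model.predict(row)[0])
                if rf_model is not None and row is not None else np.nan
            )
        if "croston" in methods:
            obs = ext_hist[~np.isnan(ext_hist)]
            rec["score_croston"] = (
                float(croston_forecast(obs, alpha=alpha)[-1]) if len(obs) else 0.0
            )

        if ext_mode == "sequential":
            cur = build_ext(counts, upto=t, **ext_kw)
            truth = cur["ext"].iloc[t - 1]
            prev = cur
        rec["truth"] = float(truth) if not np.isnan(truth) else np.nan
        records.append(rec)
        if progress and step % 100 == 0:
            print(f"  origin {t}/{n}")

    log = pd.DataFrame.from_records(records).set_index("date")
    front = ["truth"] + [f"score_{m}" for m in methods]
    return log[front + [c for c in log.columns if c not in front]]
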