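"""Construction of the binary series of extremely high stroke days.

The pipeline is: 7-day trailing rolling sum of the daily counts →
detrending with a cubic smoothing spline → dynamic binarization against
the 90th percentile of the detrended values *strictly before* each day.
A day is "extreme" when its smoothed, detrended value strictly surpasses
that historical percentile; ties and sub-threshold days are 0. Days with
too little history (the rolling warm-up plus ``min_history`` days) are
left missing.

Because thresholds only look backwards and the rolling windows are
trailing, the construction can be re-run on any truncated history without
future leakage, which is what the sequential forecasting harness does.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import eigh, solve_triangular

__all__ = [
    "rolling_sum", "rolling_mean", "detrend_spline", "default_nknots",
    "binarize_past_percentile", "binarize_fixed_first_n", "build_ext",
]


def _rolling(series: pd.Series, window: int, how: str) -> pd.Series:
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    roll = series.rolling(window=window, min_periods=window)
    out = roll.sum() if how == "sum" else roll.mean()
    # min_periods=window makes any missing value inside the window (and the
    # first window-1 days) propagate as missing, which is what we want:
    # a gap in the registry should not silently deflate the weekly load.
    return out


def rolling_sum(series: pd.Series, window: int = 7) -> pd.Series:
    """Trailing ``window``-day sum; value at t covers days t-window+1 … t."""
    return _rolling(series, window, "sum")


def rolling_mean(series: pd.Series, window: int = 7) -> pd.Series:
    """Trailing ``window``-day mean (used for the meteorological series)."""
    return _rolling(series, window, "mean")


def default_nknots(n: int) -> int:
    """Knot count for the penalized regression spline, as a function of
    the number of data points.

    Grows like the rule used by classical smoothing-spline software
    (roughly 100 knots at n=200 rising to 200 at n=3200, then very
    slowly): enough flexibility for seasonal and multi-month structure
    while keeping the basis far smaller than the data, which both speeds
    up the fit and keeps GCV from chasing the serial noise that a 7-day
    rolling sum carries.
    """
    if n < 50:
        return n
    a1, a2, a3, a4 = np.log2([50.0, 100.0, 140.0, 200.0])
    if n < 200:
        k = 2.0 ** (a1 + (a2 - a1) * (n - 50) / 150.0)
    elif n < 800:
        k = 2.0 ** (a2 + (a3 - a2) * (n - 200) / 600.0)
    elif n < 3200:
        k = 2.0 ** (a3 + (a4 - a3) * (n - 800) / 2400.0)
    else:
        k = 200.0 + (n - 3200.0) ** 0.2
    return int(k)


class PenalizedSplineFit:
    """Cubic penalized regression spline with GCV-selected penalty.

    The trend is a cubic B-spline over ``nknots`` equally spaced knots
    penalized by the exact curvature functional ``∫ f''(s)² ds`` (computed
    by two-point Gauss quadrature per knot span, exact for the piecewise
    quadratic integrand), so straight lines are never penalized. With the
    coefficient problem reduced to the knot basis, a single
    eigendecomposition gives the whole GCV curve cheaply:

    ``beta(λ) = (BᵀB + λDᵀD)⁻¹ Bᵀy``,
    ``GCV(λ) = n·RSS(λ) / (n − tr H(λ))²``.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray,
                 lam: float | None = None, nknots: int | None = None):
        n = len(x)
        k = min(nknots or default_nknots(n), n)
        degree = 3
        inner = np.linspace(x[0], x[-1], k)
        t = np.r_[[x[0]] * degree, inner, [x[-1]] * degree]
        B = BSpline.design_matrix(x, t, degree)  # sparse (n, k+2)
        p = B.shape[1]
        BtB = (B.T @ B).toarray()
        Bty = B.T @ y
        P = self._curvature_penalty(t, p, degree)
        # reduce to an ordinary eigenproblem in the BtB metric:
        # BtB = LLᵀ, M = L⁻¹ P L⁻ᵀ = W S Wᵀ, V = L⁻ᵀ W  (Vᵀ BtB V = I,
        # Vᵀ P V = S), so (BtB + λP)⁻¹ = V (I + λS)⁻¹ Vᵀ.
        eps = 1e-8 * float(np.mean(np.diag(BtB)))
        L = np.linalg.cholesky(BtB + eps * np.eye(p))
        Linv = solve_triangular(L, np.eye(p), lower=True)
        M = Linv @ P @ Linv.T
        s, W = eigh(M)
        s = np.clip(s, 0.0, None)
        V = Linv.T @ W
        cvec = V.T @ Bty
        yty = float(y @ y)

        def stats(lam_: float) -> tuple[float, float]:
            d = cvec / (1.0 + lam_ * s)
            rss = yty - 2.0 * float(d @ cvec) + float(d @ d)
            tr = float(np.sum(1.0 / (1.0 + lam_ * s)))
            return max(rss, 0.0), tr

        if lam is None:
            def gcv(log_lam: float) -> float:
                rss, tr = stats(10.0 ** log_lam)
                return n * rss / (n - tr) ** 2

            phi = (np.sqrt(5.0) - 1.0) / 2.0
            a, b = -4.0, 12.0
            cc, dd = b - phi * (b - a), a + phi * (b - a)
            fc, fd = gcv(cc), gcv(dd)
            while b - a > 1e-3:
                if fc < fd:
                    b, dd, fd = dd, cc, fc
                    cc = b - phi * (b - a)
                    fc = gcv(cc)
                else:
                    a, cc, fc = cc, dd, fd
                    dd = a + phi * (b - a)
                    fd = gcv(dd)
            lam = float(10.0 ** ((a + b) / 2.0))
        d = cvec / (1.0 + lam * s)
        beta = V @ d
        self.lam = float(lam)
        self.edf = float(np.sum(1.0 / (1.0 + lam * s)))
        self.spline = BSpline(t, beta, degree)
        self.fitted = B @ beta

    @staticmethod
    def _curvature_penalty(t: np.ndarray, p: int, degree: int) -> np.ndarray:
        """Gram matrix of second derivatives, ∫ B_i'' B_j'' ds."""
        spans = np.unique(t)
        a, b = spans[:-1], spans[1:]
        half = (b - a) / 2.0
        mid = (a + b) / 2.0
        offs = half / np.sqrt(3.0)  # 2-point Gauss-Legendre
        pts = np.r_[mid - offs, mid + offs]
        wts = np.r_[half, half]
        d2 = BSpline(t, np.eye(p), degree).derivative(2)(pts)
        return (d2 * wts[:, None]).T @ d2

    def __call__(self, xnew: np.ndarray) -> np.ndarray:
        return self.spline(xnew)


def detrend_spline(series: pd.Series, smoothing: str | float = "gcv",
                   nknots: int | None = None) -> pd.DataFrame:
    """Fit a cubic smoothing-spline trend and return value/trend/residual.

    Parameters
    ----------
    series
        Daily numeric series (typically a 7-day rolling sum); missing
        values are ignored for the fit and stay missing in the output.
    smoothing
        ``"gcv"`` selects the penalty by generalized cross-validation; a
        positive float fixes the penalty λ of :class:`PenalizedSplineFit`.
    nknots
        Basis size; default grows slowly with the series length
        (:func:`default_nknots`).

    Returns
    -------
    DataFrame with columns ``value``, ``trend``, ``residual`` on the input
    calendar; ``residual + trend == value`` exactly where defined. The
    chosen penalty and effective degrees of freedom are stored in
    ``.attrs["lam"]`` and ``.attrs["edf"]``.
    """
    clean = series.dropna()
    if len(clean) < 10:
        raise ValueError(f"need >= 10 non-missing points, got {len(clean)}")
    pos = np.flatnonzero(series.notna().to_numpy())
    x = pos.astype(float)
    y = clean.to_numpy(dtype=float)
    if smoothing == "gcv":
        fit = PenalizedSplineFit(x, y, lam=None, nknots=nknots)
    else:
        lam = float(smoothing)
        if lam <= 0:
            raise ValueError("smoothing penalty must be positive")
        fit = PenalizedSplineFit(x, y, lam=lam, nknots=nknots)
    trend = pd.Series(np.nan, index=series.index, name="trend")
    trend.iloc[pos] = fit.fitted
    out = pd.DataFrame({"value": series, "trend": trend})
    out["residual"] = out["value"] - out["trend"]
    out.attrs["lam"] = fit.lam
    out.attrs["edf"] = fit.edf
    return out


def binarize_past_percentile(series: pd.Series, q: float = 0.90,
                             min_history: int = 100) -> pd.DataFrame:
    """Dynamic binarization against the running past ``q``-quantile.

    For each day t with at least ``min_history`` prior non-missing values,
    the cutoff is the ``q``-quantile (linear interpolation between order
    statistics) of the values strictly before t, and the day is extreme
    (1) iff its value strictly exceeds the cutoff. Days before the history
    requirement is met are warm-up and stay missing.

    Returns a DataFrame with columns ``ext`` (0/1/NaN) and ``cutoff``.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile q must be in (0, 1), got {q}")
    if min_history < 10:
        raise ValueError("min_history must be >= 10")
    values = series.to_numpy(dtype=float)
    # cutoff at t = expanding quantile over values < t  ==  shifted expanding
    cutoff = (
        series.shift(1).expanding(min_periods=min_history).quantile(q, interpolation="linear")
    )
    # a missing value on day t must not flip ext to 0/1
    ext = pd.Series(np.nan, index=series.index, name="ext")
    ready = cutoff.notna() & series.notna()
    ext[ready] = (values[ready.to_numpy()] > cutoff[ready].to_numpy()).astype(float)
    cutoff[series.isna()] = np.nan
    return pd.DataFrame({"ext": ext, "cutoff": cutoff})


def binarize_fixed_first_n(series: pd.Series, q: float = 0.90,
                           n_init: int = 500) -> pd.DataFrame:
    """Binarize against a single cutoff from the first ``n_init`` values.

    The simpler, non-adaptive alternative to the dynamic rule: the cutoff
    is the ``q``-quantile of the first ``n_init`` non-missing values and is
    then applied (strict inequality) to every later day. The initial
    segment itself is warm-up.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile q must be in (0, 1), got {q}")
    clean = series.dropna()
    if len(clean) <= n_init:
        raise ValueError(f"series has {len(clean)} values, need > n_init={n_init}")
    thr = float(np.quantile(clean.to_numpy()[:n_init], q))
    boundary = clean.index[n_init - 1]
    ext = pd.Series(np.nan, index=series.index, name="ext")
    after = (series.index > boundary) & series.notna()
    ext[after] = (series[after].to_numpy(dtype=float) > thr).astype(float)
    cutoff = pd.Series(np.nan, index=series.index, name="cutoff")
    cutoff[after] = thr
    return pd.DataFrame({"ext": ext, "cutoff": cutoff})


def build_ext(counts: pd.Series, upto: int | None = None, *, window: int = 7,
              q: float = 0.90, min_history: int = 100,
              smoothing: str | float = "gcv", mode: str = "dynamic",
              n_init: int = 500) -> pd.DataFrame:
    """Full extreme-day construction on (a truncation of) a count series.

    Parameters
    ----------
    counts
        Daily count series on a full calendar.
    upto
        1-based day index at which to truncate the series before the
        construction (inclusive); ``None`` uses the whole series. The
        sequential harness calls this with growing ``upto`` so that day-t
        ground truth never sees data after t.
    mode
        ``"dynamic"`` for the past-percentile rule, ``"fixed"`` for the
        fixed first-``n_init`` threshold.

    Returns
    -------
    DataFrame with columns ``roll_sum``, ``trend``, ``residual``,
    ``cutoff``, ``ext`` on the truncated calendar.
    """
    if upto is not None:
        if not (1 <= upto <= len(counts)):
            raise ValueError(f"upto={upto} outside series of length {len(counts)}")
        counts = counts.iloc[:upto]
    roll = rolling_sum(counts, window=window)
    if roll.notna().sum() < max(10, min_history + 1):
        raise ValueError("insufficient history for extreme-day construction")
    det = detrend_spline(roll, smoothing=smoothing)
    if mode == "dynamic":
        binar = binarize_past_percentile(det["residual"], q=q, min_history=min_history)
    elif mode == "fixed":
        binar = binarize_fixed_first_n(det["residual"], q=q, n_init=n_init)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame({
        "roll_sum": roll,
        "trend": det["trend"],
        "residual": det["residual"],
        "cutoff": binar["cutoff"],
        "ext": binar["ext"],
    })
    out.attrs.update(det.attrs)
    return out
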