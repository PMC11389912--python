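"""Forecast evaluation: ROC/AUC, Youden operating point, paired bootstrap
AUC-equality tests with Benjamini–Hochberg adjustment, and cross-correlation
screening with white-noise confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "auc", "roc_points", "youden_point", "paired_bootstrap_auc_test",
    "bh_adjust", "ccf", "CcfResult", "evaluate_log",
]


def _check_classes(truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=float)
    pos = truth == 1
    neg = truth == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    return pos, neg


def auc(truth, scores) -> float:
    """Area under the ROC curve, Mann–Whitney formulation.

    The fraction of (positive, negative) day pairs where the positive day
    received the higher score, ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_classes(np.asarray(truth))
    ranks = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(truth, scores) -> pd.DataFrame:
    """Empirical ROC curve (fpr, tpr, threshold), thresholds decreasing."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float)
    pos, neg = _check_classes(truth)
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    tp = np.cumsum(truth[order] == 1)
    fp = np.cumsum(truth[order] == 0)
    last = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp[last] / pos.sum()]
    fpr = np.r_[0.0, fp[last] / neg.sum()]
    thr = np.r_[np.inf, sorted_scores[last]]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def youden_point(truth, scores) -> tuple[float, float, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity − 1.

    Candidate thresholds are the midpoints between adjacent distinct
    scores plus ∓∞ sentinels; a day is called positive when its score is
    strictly above the threshold. Among maximizers the smallest threshold
    (the most sensitive operating point) is returned — in a surge-warning
    setting a missed surge is the costly error.

    Returns ``(threshold, sensitivity, specificity)``.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float)
    pos, neg = _check_classes(truth)
    uniq = np.unique(scores)
    candidates = np.r_[-np.inf, (uniq[1:] + uniq[:-1]) / 2.0, np.inf]
    best = (-np.inf, np.nan, np.nan, np.nan)
    n_pos, n_neg = pos.sum(), neg.sum()
    for thr in candidates:
        called = scores > thr
        sens = float((called & pos).sum() / n_pos)
        spec = float((~called & neg).sum() / n_neg)
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    return best[1], best[2], best[3]


def paired_bootstrap_auc_test(truth, scores_a, scores_b, B: int = 2000,
                              seed: int = 0) -> float:
    """Two-sided paired bootstrap test of AUC equality.

    Days are resampled with replacement, stratified by class so every
    replicate keeps both classes, jointly for the two score vectors and
    the shared truth (paired mode). The p-value is
    ``2·min(P(ΔAUC ≤ 0), P(ΔAUC ≥ 0))`` with the add-one small-sample
    correction ``(count + 1)/(B + 1)``, capped at 1. Deterministic for a
    fixed seed.
    """
    truth = np.asarray(truth, dtype=float)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (len(truth) == len(a) == len(b)):
        raise ValueError("truth and score vectors must have equal length")
    pos, neg = _check_classes(truth)
    pos_idx = np.flatnonzero(pos)
    neg_idx = np.flatnonzero(neg)
    rng = np.random.default_rng(np.uint32(seed))
    deltas = np.empty(B)
    for i in range(B):
        p = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        n = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.r_[p, n]
        t = truth[idx]
        deltas[i] = auc(t, a[idx]) - auc(t, b[idx])
    p_le = (np.sum(deltas <= 0.0) + 1.0) / (B + 1.0)
    p_ge = (np.sum(deltas >= 0.0) + 1.0) / (B + 1.0)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CcfResult:
    """Cross-correlation of x(t+k) with y(t) for k = −max_lag … max_lag."""

    lags: np.ndarray
    values: np.ndarray
    band: float  # ±1.96/√n white-noise band halfwidth
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags, "ccf": self.values,
                             "band": self.band})

    def outside_band(self) -> np.ndarray:
        return np.abs(self.values) > self.band


def ccf(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray,
        max_lag: int = 15) -> CcfResult:
    """Cross-correlation function between an outcome and an exposure series.

    The value at lag k is the correlation between ``x`` at time t+k and
    ``y`` at time t; positive lags therefore measure how the exposure
    leads the outcome. Aligned on the common calendar when both inputs
    carry date indexes; rows where either series is missing are dropped.
    Normalization uses the full-series standard deviations with divisor n
    (the conventional estimator), so |ccf| ≤ 1 is not strictly guaranteed
    at large lags but holds in practice.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        common = x.index.intersection(y.index)
        x = x.reindex(common)
        y = y.reindex(common)
        keep = x.notna() & y.notna()
        xv = x[keep].to_numpy(dtype=float)
        yv = y[keep].to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        keep = ~(np.isnan(xv) | np.isnan(yv))
        xv, yv = xv[keep], yv[keep]
    n = len(xv)
    if n <= 3 * max_lag:
        raise ValueError(f"need more than {3 * max_lag} overlapping points, got {n}")
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    xc, yc = xv - xv.mean(), yv - yv.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            s = np.sum(xc[k:] * yc[: n - k])
        else:
            s = np.sum(xc[: n + k] * yc[-k:])
        vals[i] = s / (n * sx * sy)
    return CcfResult(lags=lags, values=vals, band=float(1.96 / np.sqrt(n)), n=n)


# --------------------------------------------------------------------------
# report assembly

def evaluate_log(log: pd.DataFrame, *, B: int = 2000, seed: int = 0,
                 methods: list[str] | None = None) -> dict:
    """Evaluate a sequential forecast log into a JSON-ready report.

    Expects the log columns ``truth`` and ``score_<method>``; days with a
    missing truth or score for a given method are excluded from that
    method's metrics (pairwise comparisons use days complete for both).
    """
    if methods is None:
        methods = [c.removeprefix("score_") for c in log.columns
                   if c.startswith("score_")]
    report: dict = {"methods": {}, "comparisons": {},
                    "settings": {"B": B, "seed": int(seed),
                                 "n_days": int(len(log))}}
    truth = log["truth"]
    for m in methods:
        s = log[f"score_{m}"]
        ok = truth.notna() & s.notna()
        t, sv = truth[ok].to_numpy(), s[ok].to_numpy()
        thr, sens, spec = youden_point(t, sv)
        report["methods"][m] = {
            "auc": auc(t, sv),
            "youden_threshold": float(thr),
            "sensitivity": sens,
            "specificity": spec,
            "n_scored": int(ok.sum()),
            "n_extreme": int(t.sum()),
        }
    pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1:]]
    raw = []
    for a, b in pairs:
        sa, sb = log[f"score_{a}"], log[f"score_{b}"]
        ok = truth.notna() & sa.notna() & sb.notna()
        raw.append(paired_bootstrap_auc_test(
            truth[ok].to_numpy(), sa[ok].to_numpy(), sb[ok].to_numpy(),
            B=B, seed=seed))
    adj = bh_adjust(raw) if raw else []
    for (a, b), p, padj in zip(pairs, raw, adj):
        report["comparisons"][f"{a}_vs_{b}"] = {
            "auc_diff": report["methods"][a]["auc"] - report["methods"][b]["auc"],
            "p_value": float(p),
            "p_adjusted": float(padj),
        }
    return report
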