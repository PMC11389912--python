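"""The three one-step-ahead forecasters.

* multivariate logistic regression (GLM with binomial family), fitted by
  iteratively reweighted least squares, with optional backward AIC term
  selection, McFadden pseudo-R² and BIC;
* a random-forest classifier over the same lagged design ("random forest
  for time series"), with Gini impurity importances and permutation
  importances, and an optional moving-block bootstrap for tree resampling;
* Croston's intermittent-demand method on the binary extreme series
  alone: exponentially smoothed nonzero event size and inter-event
  interval, forecast = size / interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import qr as _pivoted_qr
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import LagDesign

__all__ = [
    "LogisticModel", "fit_logistic", "stepwise_aic", "mcfadden_r2",
    "ForestModel", "fit_forest",
    "CrostonState", "croston_update", "croston_forecast",
]


# --------------------------------------------------------------------------
# logistic regression

@dataclass
class LogisticModel:
    """A fitted binomial GLM on a (possibly reduced) design."""

    params: np.ndarray            # coefficients for the kept columns
    columns: list[str]            # kept column names
    kept: np.ndarray              # indices into the original design columns
    dropped: list[str]            # aliased columns removed by the rank guard
    cov: np.ndarray               # inverse observed information (kept columns)
    loglik: float
    loglik_null: float
    n: int
    converged: bool
    separated: bool
    terms: list[str] | None = None  # term names, when fitted from a LagDesign

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n)

    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Event probabilities for rows of the *original* design layout."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = X[:, self.kept] @ self.params
        return _sigmoid(eta)

    def params_full(self, n_columns: int) -> np.ndarray:
        """Coefficients embedded in the original column layout (zeros at
        aliased positions) — usable as a warm start for a refit whose
        aliasing pattern may differ."""
        full = np.zeros(n_columns)
        full[self.kept] = self.params
        return full


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35.0, 35.0)))


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (QR pivoting)."""
    _, R, piv = _pivoted_qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return np.sort(piv[:rank])


def fit_logistic(design: LagDesign | np.ndarray, y: np.ndarray | None = None, *,
                 tol: float = 1e-8, max_iter: int = 100,
                 start_params: np.ndarray | None = None,
                 keep: np.ndarray | None = None) -> LogisticModel:
    """Maximum-likelihood logistic regression via IRLS.

    Parameters
    ----------
    design, y
        Either a :class:`~strokecast.features.LagDesign` (whose response
        is used) or a raw predictor matrix plus response vector. The
        matrix is expected to contain its own intercept column.
    tol
        Convergence tolerance on the deviance change.
    start_params
        Warm start: either coefficients for the kept columns or a
        full-design-length vector (see :meth:`LogisticModel.params_full`),
        which is subset to the kept columns after aliasing detection;
        ignored if neither length matches.
    keep
        Precomputed indices of non-aliased columns; when omitted, exactly
        collinear columns are detected by pivoted QR and dropped.

    Notes
    -----
    Complete separation is detected (every observation classified
    perfectly with diverging coefficients) and flagged rather than raised:
    the fitted probabilities are still usable as forecast scores.
    """
    if isinstance(design, LagDesign):
        X, yv, columns = design.X, design.y, design.columns
        terms = list(design.terms)
    else:
        X = np.asarray(design, dtype=float)
        yv = np.asarray(y, dtype=float)
        columns = [f"x{i}" for i in range(X.shape[1])]
        terms = None
    yv = yv.astype(float)
    classes = np.unique(yv)
    if len(classes) < 2:
        raise ValueError("response has a single class; cannot fit logistic model")
    if X.shape[0] <= X.shape[1]:
        raise ValueError(f"need n > p, got n={X.shape[0]}, p={X.shape[1]}")

    if keep is None:
        keep = _independent_columns(X)
    keep = np.asarray(keep, dtype=int)
    dropped = [columns[i] for i in range(X.shape[1]) if i not in set(keep.tolist())]
    Xk = X[:, keep]
    n, p = Xk.shape

    beta = np.zeros(p)
    if start_params is not None:
        sp = np.asarray(start_params, dtype=float)
        if len(sp) == X.shape[1]:
            beta = sp[keep].copy()
        elif len(sp) == p:
            beta = sp.copy()
    dev = np.inf
    converged = False
    for _ in range(max_iter):
        eta = Xk @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (yv - mu) / w
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(Xk * sw[:, None], z * sw, rcond=None)
        new_dev = -2.0 * _bernoulli_loglik(yv, _sigmoid(Xk @ beta))
        if abs(dev - new_dev) < tol * (abs(new_dev) + 0.1):
            converged = True
            dev = new_dev
            break
        dev = new_dev

    mu = _sigmoid(Xk @ beta)
    loglik = _bernoulli_loglik(yv, mu)
    pbar = yv.mean()
    loglik_null = float(n * (pbar * np.log(pbar) + (1.0 - pbar) * np.log(1.0 - pbar)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (Xk * w[:, None]).T @ Xk
    cov = np.linalg.pinv(info)
    separated = bool(
        np.all((mu > 0.5) == (yv > 0.5)) and float(np.abs(Xk @ beta).min()) > 10.0
    )
    return LogisticModel(
        params=beta, columns=[columns[i] for i in keep], kept=keep,
        dropped=dropped, cov=cov, loglik=loglik, loglik_null=loglik_null,
        n=n, converged=converged, separated=separated, terms=terms,
    )


def mcfadden_r2(model: LogisticModel) -> float:
    """McFadden pseudo-R²: 1 − ℓ(model)/ℓ(null)."""
    return 1.0 - model.loglik / model.loglik_null


def stepwise_aic(design: LagDesign, *, direction: str = "backward",
                 verbose: bool = False) -> LogisticModel:
    """Greedy backward elimination of whole terms by AIC.

    Starting from the full model, each step refits the model without each
    removable term in turn (categorical terms leave as a block) and drops
    the term whose removal lowers AIC most; stops when no removal helps.
    The intercept is never removed.
    """
    if direction != "backward":
        raise ValueError("only backward elimination is implemented")
    current_terms = list(design.terms)
    current = fit_logistic(design)
    current_aic = current.aic
    while True:
        best = None
        for term in current_terms:
            if term == "Intercept":
                continue
            candidate_terms = [t for t in current_terms if t != term]
            try:
                cand = fit_logistic(design.subset(candidate_terms))
            except ValueError:
                continue
            if best is None or cand.aic < best[1]:
                best = (term, cand.aic, cand, candidate_terms)
        if best is None or best[1] >= current_aic:
            break
        term, current_aic, current, current_terms = best
        if verbose:
            print(f"dropped {term}: AIC {current_aic:.2f}")
    current.terms = current_terms
    return current


# --------------------------------------------------------------------------
# random forest

@dataclass
class ForestModel:
    """A fitted random-forest classifier over the lagged design."""

    estimator: object
    columns: list[str]
    kept: np.ndarray
    classes_: np.ndarray
    n_trees: int
    seed: int
    importance_impurity: np.ndarray = field(default=None)
    _train: tuple = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """P(extreme) for rows of the original design layout."""
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, self.kept]
        proba = self.estimator.predict_proba(X)
        if len(self.classes_) == 1:  # degenerate single-class training window
            return np.full(X.shape[0], float(self.classes_[0]))
        return proba[:, list(self.classes_).index(1.0)]

    def permutation_importance(self, n_repeats: int = 5,
                               seed: int | None = None) -> np.ndarray:
        """Permutation importance (mean accuracy drop) on the training data."""
        from sklearn.inspection import permutation_importance as sk_perm

        X, y = self._train
        res = sk_perm(self.estimator, X, y, n_repeats=n_repeats,
                      random_state=self.seed if seed is None else seed, n_jobs=1)
        return res.importances_mean


class _BlockBootstrapForest:
    """A bagged ensemble whose per-tree resamples are moving blocks.

    Standard bootstrap resampling breaks serial dependence; resampling
    contiguous blocks of days keeps short-range autocorrelation inside
    each tree's training sample. Interface-compatible with the sklearn
    estimator for the needs of :class:`ForestModel`.
    """

    def __init__(self, n_trees: int, block_length: int, mtry, seed: int):
        self.n_trees = n_trees
        self.block_length = block_length
        self.mtry = mtry
        self.seed = seed
        self.trees: list[DecisionTreeClassifier] = []

    def fit(self, X: np.ndarray, y: np.ndarray):
        rng = np.random.default_rng(np.uint32(self.seed))
        n = len(y)
        L = min(self.block_length, n)
        n_blocks = int(np.ceil(n / L))
        self.classes_ = np.unique(y)
        self.trees = []
        imp = np.zeros(X.shape[1])
        for i in range(self.n_trees):
            starts = rng.integers(0, n - L + 1, size=n_blocks)
            idx = (starts[:, None] + np.arange(L)[None, :]).ravel()[:n]
            tree = DecisionTreeClassifier(
                max_features=self.mtry,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            imp += tree.feature_importances_
            self.trees.append(tree)
        self.feature_importances_ = imp / self.n_trees
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros((X.shape[0], len(self.classes_)))
        lookup = {c: j for j, c in enumerate(self.classes_)}
        for tree in self.trees:
            p = tree.predict_proba(X)
            for j, c in enumerate(tree.classes_):
                out[:, lookup[c]] += p[:, j]
        return out / len(self.trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # minimal sklearn-estimator compatibility for permutation_importance
    def get_params(self, deep=True):
        return {"n_trees": self.n_trees, "block_length": self.block_length,
                "mtry": self.mtry, "seed": self.seed}

    def score(self, X, y):
        return float(np.mean(self.predict(X) == y))


def fit_forest(design: LagDesign | np.ndarray, y: np.ndarray | None = None, *,
               n_trees: int = 500, mtry: str | int = "sqrt", seed: int = 0,
               bootstrap: str = "iid", block_length: int = 10,
               keep: np.ndarray | None = None) -> ForestModel:
    """Fit the random forest on the lagged design.

    ``bootstrap="iid"`` is the standard per-observation bootstrap;
    ``"block"`` resamples moving blocks of ``block_length`` consecutive
    days instead. A single-class response is tolerated (an early expanding
    window may contain no extreme days yet) and scored as that constant
    class. Deterministic for a fixed seed.
    """
    if isinstance(design, LagDesign):
        X, yv, columns = design.X, design.y, design.columns
    else:
        X = np.asarray(design, dtype=float)
        yv = np.asarray(y, dtype=float)
        columns = [f"x{i}" for i in range(X.shape[1])]
    keep = np.arange(X.shape[1]) if keep is None else np.asarray(keep, dtype=int)
    Xk = X[:, keep]
    if bootstrap == "iid":
        est = RandomForestClassifier(
            n_estimators=n_trees, max_features=mtry,
            random_state=int(seed) % (2**31 - 1), n_jobs=1,
        )
    elif bootstrap == "block":
        est = _BlockBootstrapForest(n_trees, block_length, mtry, int(seed))
    else:
        raise ValueError(f"unknown bootstrap {bootstrap!r}")
    est.fit(Xk, yv)
    return ForestModel(
        estimator=est, columns=[columns[i] for i in keep], kept=keep,
        classes_=np.unique(yv), n_trees=n_trees, seed=int(seed),
        importance_impurity=np.asarray(est.feature_importances_),
        _train=(Xk, yv),
    )


# --------------------------------------------------------------------------
# Croston's method

@dataclass(frozen=True)
class CrostonState:
    """State of Croston's intermittent-demand recursion.

    ``z_hat`` smooths the nonzero event sizes, ``p_hat`` the inter-event
    intervals (days); the one-step-ahead forecast rate is ``z_hat/p_hat``.
    Before the first nonzero observation the forecast is 0 by convention.
    Initialization uses the first nonzero value and its 1-based position.
    """

    alpha: float = 0.5
    z_hat: float = np.nan
    p_hat: float = np.nan
    periods_since_demand: int = 0
    n_seen: int = 0
    initialized: bool = False

    @property
    def forecast(self) -> float:
        return self.z_hat / self.p_hat if self.initialized else 0.0


def croston_update(state: CrostonState, observation: float) -> tuple[CrostonState, float]:
    """Advance Croston's recursion by one observation.

    On a nonzero observation z arriving q periods after the previous one:
    ``z_hat ← α·z + (1−α)·z_hat`` and ``p_hat ← α·q + (1−α)·p_hat``; a zero
    observation only increments the inter-demand counter. Returns the new
    state and the one-step-ahead forecast after this observation.
    """
    if not (0.0 < state.alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {state.alpha}")
    if observation < 0:
        raise ValueError("negative observation")
    a = state.alpha
    if observation == 0:
        state = replace(state, periods_since_demand=state.periods_since_demand + 1,
                        n_seen=state.n_seen + 1)
    elif not state.initialized:
        state = replace(state, z_hat=float(observation), p_hat=float(state.n_seen + 1),
                        periods_since_demand=0, n_seen=state.n_seen + 1,
                        initialized=True)
    else:
        q = state.periods_since_demand + 1
        state = replace(
            state,
            z_hat=a * float(observation) + (1.0 - a) * state.z_hat,
            p_hat=a * float(q) + (1.0 - a) * state.p_hat,
            periods_since_demand=0, n_seen=state.n_seen + 1,
        )
    return state, state.forecast


def croston_forecast(series: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """One-step-ahead Croston forecasts along a series.

    ``out[i]`` is the forecast available after observing ``series[:i+1]``,
    i.e. the prediction for step i+1.
    """
    state = CrostonState(alpha=alpha)
    out = np.empty(len(series))
    for i, obs in enumerate(np.asarray(series, dtype=float)):
        state, out[i] = croston_update(state, obs)
    return out
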