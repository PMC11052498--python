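"""PLS1 regression (NIPALS) with leave-one-out cross-validation.

The regressor projects a wide, collinear descriptor matrix (holograms or
lattice fields) onto a few latent components and is the modelling engine
behind every QSAR variant in this package.  Internal quality is judged by

* ``r^2``  -- non-cross-validated squared correlation of fitted vs
  observed activities,
* ``q^2``  -- leave-one-out cross-validated determination coefficient,
  ``1 - PRESS / sum (y_i - ybar)^2`` with each prediction from a model
  refit without that compound,
* ``SEE``  -- sqrt(RSS / (n - N - 1)), the component-adjusted standard
  error of estimate, and the corresponding F statistic.

The component count is chosen by maximizing LOO q^2 (ties toward the
smaller model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PLSRegressionNIPALS",
    "PLSModelState",
    "fit_pls",
    "loo_q2",
    "loo_predictions",
    "training_stats",
    "select_components",
]


class PLSRegressionNIPALS(RegressorMixin, BaseEstimator):
    """Univariate-response PLS fitted by NIPALS on centered data.

    Parameters
    ----------
    n_components : int
        Number of latent components N (>= 1).
    scale : bool
        Autoscale descriptor columns to unit variance (default off;
        lattice-field and hologram blocks are conventionally used
        unscaled so that large-variance regions dominate).
    tol, max_iter : float, int
        NIPALS convergence tolerance and iteration cap per component.

    Fitted attributes (trailing underscore) include ``coef_``,
    ``intercept_``, ``x_scores_``, ``x_weights_``, ``x_loadings_`` and
    ``n_components_``; predictions are reproducible from ``coef_`` and
    ``intercept_`` alone.
    """

    def __init__(self, n_components: int = 2, scale: bool = False,
                 tol: float = 1e-10, max_iter: int = 500):
        self.n_components = n_components
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, m = X.shape
        if len(y) != n:
            raise ValueError("X and y disagree on the number of samples")
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("X and y must be finite (no missing values)")
        N = int(self.n_components)
        if N < 1:
            raise ValueError("n_components must be >= 1")
        if N >= n:
            raise ValueError(f"n_components={N} must be < n samples={n}")

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        self.x_std_ = X.std(axis=0, ddof=1) if self.scale else np.ones(m)
        self.x_std_ = np.where(self.x_std_ > 0, self.x_std_, 1.0)
        Xc = (X - self.x_mean_) / self.x_std_
        yc = y - self.y_mean_

        if np.allclose(yc, 0.0):
            warnings.warn("zero-variance response: degenerate model (intercept only)")
            self.coef_ = np.zeros(m)
            self.intercept_ = self.y_mean_
            self.x_weights_ = np.zeros((m, 0))
            self.x_loadings_ = np.zeros((m, 0))
            self.x_scores_ = np.zeros((n, 0))
            self.y_loadings_ = np.zeros(0)
            self.n_components_ = 0
            return self

        W = np.zeros((m, N))
        P = np.zeros((m, N))
        T = np.zeros((n, N))
        q = np.zeros(N)
        Xd, yd = Xc.copy(), yc.copy()
        k_eff = 0
        for k in range(N):
            w = Xd.T @ yd
            wn = np.linalg.norm(w)
            if wn < 1e-14:
                warnings.warn(f"descriptors exhausted after {k} components")
                break
            w /= wn
            # NIPALS iteration; for a single response it converges at once
            for _ in range(self.max_iter):
                t = Xd @ w
                qk = (yd @ t) / (t @ t)
                w_new = Xd.T @ (yd * qk)
                w_new /= np.linalg.norm(w_new)
                if np.linalg.norm(w_new - w) < self.tol:
                    w = w_new
                    break
                w = w_new
            t = Xd @ w
            tt = t @ t
            p = Xd.T @ t / tt
            qk = (yd @ t) / tt
            W[:, k], P[:, k], T[:, k], q[k] = w, p, t, qk
            Xd = Xd - np.outer(t, p)
            yd = yd - qk * t
            k_eff += 1

        W, P, T, q = W[:, :k_eff], P[:, :k_eff], T[:, :k_eff], q[:k_eff]
        if k_eff:
            beta = W @ np.linalg.solve(P.T @ W, q)
        else:
            beta = np.zeros(m)
        self.coef_ = beta / self.x_std_
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.x_weights_, self.x_loadings_, self.x_scores_ = W, P, T
        self.y_loadings_ = q
        self.n_components_ = k_eff
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


@dataclass(frozen=True)
class PLSModelState:
    """Fitted PLS model plus its internal statistics."""

    n_components: int
    coefficients: np.ndarray
    intercept: float
    q2: Optional[float]
    r2: float
    see: float
    see_cv: Optional[float]
    f_statistic: float

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept


def fit_pls(X, y, n_components: int, scale: bool = False,
            compute_q2: bool = True) -> PLSModelState:
    """Fit PLS and assemble the internal-statistics report."""
    est = PLSRegressionNIPALS(n_components=n_components, scale=scale).fit(X, y)
    r2, see, f = training_stats(est, X, y)
    q2 = see_cv = None
    if compute_q2:
        q2, press = _loo(X, y, n_components, scale)
        n = len(np.asarray(y).ravel())
        see_cv = float(np.sqrt(press / max(n - est.n_components_ - 1, 1)))
    return PLSModelState(
        n_components=est.n_components_, coefficients=est.coef_,
        intercept=est.intercept_, q2=q2, r2=r2, see=see, see_cv=see_cv,
        f_statistic=f,
    )


def loo_predictions(X, y, n_components: int, scale: bool = False) -> np.ndarray:
    """Leave-one-out predictions, each from a refit excluding that sample."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            est = PLSRegressionNIPALS(n_components=n_components, scale=scale)
            est.fit(X[mask], y[mask])
        except Exception as exc:
            raise RuntimeError(f"LOO refit failed on fold {i}: {exc}") from exc
        out[i] = est.predict(X[i:i + 1])[0]
    return out


def _loo(X, y, n_components, scale):
    y = np.asarray(y, dtype=float).ravel()
    yhat = loo_predictions(X, y, n_components, scale)
    press = float(((y - yhat) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss, press


def loo_q2(X, y, n_components: int, scale: bool = False) -> float:
    """Leave-one-out cross-validated q^2 = 1 - PRESS / SS_tot."""
    q2, _ = _loo(X, y, n_components, scale)
    return q2


def training_stats(model, X, y) -> tuple[float, float, float]:
    """Non-cross-validated r^2 (squared correlation), SEE and F.

    SEE uses the component-adjusted denominator n - N - 1; F is
    (r^2/N) / ((1 - r^2)/(n - N - 1)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    yhat = model.predict(X)
    n = len(y)
    N = getattr(model, "n_components_", None) or getattr(model, "n_components")
    if n <= N + 1:
        raise ValueError(f"SEE undefined: n={n} <= N+1={N + 1}")
    yc, yhc = y - y.mean(), yhat - yhat.mean()
    denom = float((yc @ yc) * (yhc @ yhc))
    r2 = float((yc @ yhc) ** 2 / denom) if denom > 0 else 0.0
    rss = float(((y - yhat) ** 2).sum())
    see = float(np.sqrt(rss / (n - N - 1)))
    f = float((r2 / N) / ((1 - r2) / (n - N - 1))) if r2 < 1 else float("inf")
    return r2, see, f


def select_components(X, y, n_max: int, scale: bool = False) -> tuple[int, list[float]]:
    """Pick the component count maximizing LOO q^2 (ties -> smaller N).

    Returns (N*, q^2 profile over 1..n_max).
    """
    n = len(np.asarray(y).ravel())
    if n_max >= n - 2:
        raise ValueError(f"n_max={n_max} must be < n - 2 = {n - 2}")
    profile = [loo_q2(X, y, k, scale) for k in range(1, n_max + 1)]
    best = int(np.argmax(profile)) + 1  # argmax returns the first maximum
    return best, profile
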