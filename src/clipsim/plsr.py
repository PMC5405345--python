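"""Partial least-squares regression via the SIMPLS algorithm.

PLSR projects predictors and response onto latent components chosen to
maximise the covariance between X-scores and y-scores; it handles the
strong collinearity of acoustic distance features that would destabilise
ordinary least squares. The decomposition is

    X = T P' + E,    y = U q' + F,    T = X_c W*,

with weights W* (n x k), X-loadings P, y-loadings q, scores T and U, and
the implied regression coefficients for the original design matrix

    beta = W* q',    y_hat = X beta + intercept.

X and y are mean-centered (no variance scaling: scaling is handled by the
upstream normalization schemes). SIMPLS deflates the cross-product vector
s = X_c' y_c against the orthonormalised X-loadings, which makes the
X-score columns mutually orthogonal. For a single response, SIMPLS and
NIPALS PLS1 yield identical fits; at k = rank(X_c) the fit coincides with
ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PLSRModel", "fit_simpls", "predict", "select_k",
           "standardized_coefficients"]


@dataclass
class PLSRModel:
    k: int
    x_weights: np.ndarray      # W*, (n, k)
    x_loadings: np.ndarray     # P,  (n, k)
    y_loadings: np.ndarray     # q,  (k,)
    x_scores: np.ndarray       # T,  (m, k), orthonormal columns
    y_scores: np.ndarray       # U,  (m, k)
    beta: np.ndarray           # (n,)
    intercept: float
    x_center: np.ndarray       # (n,)
    y_center: float
    fitted: np.ndarray         # (m,)
    feature_names: list[str] = field(default_factory=list)

    @property
    def x_residuals(self) -> np.ndarray:
        """E = X_c - T P'."""
        return self._Xc - self.x_scores @ self.x_loadings.T

    @property
    def y_residuals(self) -> np.ndarray:
        """F = y - y_hat."""
        return self._y - self.fitted

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "feature_names": self.feature_names,
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "x_center": self.x_center.tolist(),
            "y_center": self.y_center,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
        }


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def fit_simpls(X, y, k: int) -> PLSRModel:
    """Fit a k-component SIMPLS model of y on X.

    Raises if ``k`` exceeds the rank of the centered design matrix; the
    error reports the attainable maximum.
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    m, n = Xm.shape
    if yv.shape[0] != m:
        raise ValueError("X and y have different numbers of rows")
    if not (np.isfinite(Xm).all() and np.isfinite(yv).all()):
        raise ValueError("X and y must be finite")
    if not 1 <= k <= min(m - 1, n):
        raise ValueError(f"k must lie in [1, {min(m - 1, n)}], got {k}")

    x_center = Xm.mean(axis=0)
    y_center = float(yv.mean())
    Xc = Xm - x_center
    yc = yv - y_center

    if np.linalg.norm(yc) <= 1e-12 * max(1.0, np.linalg.norm(yv)):
        # constant response: the centered problem is trivially solved by beta = 0
        zeros_nk = np.zeros((n, k))
        model = PLSRModel(
            k=k, x_weights=zeros_nk, x_loadings=zeros_nk, y_loadings=np.zeros(k),
            x_scores=np.zeros((m, k)), y_scores=np.zeros((m, k)),
            beta=np.zeros(n), intercept=y_center, x_center=x_center,
            y_center=y_center, fitted=np.full(m, y_center), feature_names=names,
        )
        model._Xc = Xc
        model._y = yv
        return model

    W = np.zeros((n, k))
    P = np.zeros((n, k))
    q = np.zeros(k)
    T = np.zeros((m, k))
    U = np.zeros((m, k))
    V = np.zeros((n, k))  # orthonormal basis of X-loadings, for deflation

    s = Xc.T @ yc
    scale = np.linalg.norm(Xc) * np.linalg.norm(yc) + 1e-300
    for a in range(k):
        r = s.copy()
        t = Xc @ r
        t -= t.mean()
        normt = np.linalg.norm(t)
        if normt <= 1e-12 * scale:
            raise ValueError(
                f"k={k} exceeds the rank of the centered design matrix; "
                f"at most {a} components are attainable"
            )
        t /= normt
        r /= normt
        p = Xc.T @ t
        qa = float(yc @ t)
        u = yc * qa
        v = p.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p)
            u -= T[:, :a] @ (T[:, :a].T @ u)
        v /= np.linalg.norm(v)
        s = s - v * (v @ s)

        W[:, a], P[:, a], q[a], T[:, a], U[:, a], V[:, a] = r, p, qa, t, u, v

    beta = W @ q
    intercept = y_center - float(x_center @ beta)
    fitted = Xm @ beta + intercept
    model = PLSRModel(
        k=k, x_weights=W, x_loadings=P, y_loadings=q, x_scores=T, y_scores=U,
        beta=beta, intercept=intercept, x_center=x_center, y_center=y_center,
        fitted=fitted, feature_names=names,
    )
    model._Xc = Xc
    model._y = yv
    return model


def max_components(X) -> int:
    """Rank of the centered design matrix: the largest attainable k."""
    Xm, _ = _as_matrix(X)
    Xc = Xm - Xm.mean(axis=0)
    return int(np.linalg.matrix_rank(Xc))


def predict(model: PLSRModel, X_new) -> np.ndarray:
    """y_hat = (X_new - x_center) beta + y_center; predictions are not clipped."""
    if isinstance(X_new, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in X_new.columns]
        extra = [str(c) for c in X_new.columns if str(c) not in model.feature_names]
        if missing or extra:
            raise ValueError(
                f"design-matrix columns do not match the model "
                f"(missing: {missing}, extra: {extra})"
            )
        Xm = X_new[model.feature_names].to_numpy(float)
    else:
        Xm = np.asarray(X_new, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        if Xm.shape[1] != len(model.beta):
            raise ValueError(
                f"expected {len(model.beta)} columns, got {Xm.shape[1]}"
            )
    return Xm @ model.beta + model.intercept


def select_k(X, y, folds: int = 8, k_max: int | None = None, seed: int = 0) -> int:
    """Choose the component count by k-fold cross-validation on pairs.

    Pairs are randomly assigned to folds (seeded); the k with minimal mean
    squared held-out prediction error is returned, ties going to the
    smallest k.
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    m = Xm.shape[0]
    if m < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV")
    if k_max is None:
        k_max = min(m - m // folds - 1, Xm.shape[1])
    if k_max < 1:
        raise ValueError("k_max must be at least 1")

    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(np.arange(m) % folds)
    sse = np.zeros(k_max)
    counts = np.zeros(k_max)
    for f in range(folds):
        test = fold_of == f
        train = ~test
        for k in range(1, k_max + 1):
            try:
                model = fit_simpls(Xm[train], yv[train], k)
            except ValueError:
                sse[k - 1] = np.inf
                continue
            err = predict(model, Xm[test]) - yv[test]
            sse[k - 1] += float(err @ err)
            counts[k - 1] += test.sum()
    mse = sse / np.maximum(counts, 1)
    return int(np.argmin(mse)) + 1  # argmin takes the first (smallest) k on ties


def standardized_coefficients(model: PLSRModel, X, y) -> np.ndarray:
    """beta_std = beta * sd(column) / sd(y), for comparing predictor importance."""
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    return model.beta * Xm.std(axis=0, ddof=1) / yv.std(ddof=1)
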