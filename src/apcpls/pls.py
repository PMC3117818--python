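"""Univariate partial least squares regression (PLS1) by NIPALS.

PLS1 extracts orthogonal score components ``t_h = X w_h`` whose covariance
with the outcome is sequentially maximised under unit-norm weights.  Because
each coefficient vector lies in the row space of the (centred) design, PLS
remains well defined under perfect collinearity: on a rank-deficient design
with all ``rank(X)`` components retained it reproduces the minimum-norm
least-squares solution (Moore-Penrose pseudoinverse), and on a full-rank
design with all ``p`` components it reproduces OLS.  For the linear
age-period-cohort design this row-space property is what imposes the
implicit identification constraint ``b_age + b_cohort = b_period``.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .design import DesignMatrix

__all__ = ["PLS1Regression", "fit_pls1", "coefficients", "predict", "explained_variance"]

logger = logging.getLogger(__name__)


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Core NIPALS loop on an already centred (and possibly scaled) problem.

    Deflates X only; for a univariate outcome, deflating y as well changes
    neither weights nor coefficients.  Stops early if the deflated
    cross-product vector X^T y is numerically zero.
    Returns (W, T, P, q) with unit-norm weight columns.
    """
    n, p = Xc.shape
    Xd = Xc.copy()
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    ref = np.linalg.norm(Xc.T @ yc)
    h_done = 0
    for h in range(n_components):
        s = Xd.T @ yc
        ns = np.linalg.norm(s)
        if ns <= max(ref, 1.0) * 1e-12:
            logger.warning("X^T y numerically zero after %d components; stopping early", h)
            break
        w = s / ns
        t = Xd @ w
        tt = t @ t
        if tt <= 0:
            break
        W[:, h] = w
        T[:, h] = t
        P[:, h] = Xd.T @ t / tt
        q[h] = yc @ t / tt
        Xd -= np.outer(t, P[:, h])
        h_done += 1
    return W[:, :h_done], T[:, :h_done], P[:, :h_done], q[:h_done]


def _coef_path(W, P, q):
    """Coefficient vectors B(h) on the centred scale, for h = 0..H (p x (H+1))."""
    p, H = W.shape
    B = np.zeros((p, H + 1))
    if H:
        # R = W (P^T W)^{-1}: P^T W is upper triangular with unit-ish diagonal
        R = W @ np.linalg.inv(np.triu(P.T @ W))
        for h in range(1, H + 1):
            B[:, h] = R[:, :h] @ q[:h]
    return B


class PLS1Regression(RegressorMixin, BaseEstimator):
    """PLS regression with a single continuous outcome.

    Parameters
    ----------
    n_components : int
        Maximum number of components to extract.  Requests beyond the
        numerical rank of the centred design are truncated with a warning.
    scale : bool, default False
        Standardise columns to unit sample variance before extraction.
        Coefficients are always reported back on the original column scale.

    Attributes
    ----------
    x_weights_ : ndarray (p, H)
        Unit-norm weight vectors w_h.
    x_scores_ : ndarray (n, H)
        Orthogonal score vectors t_h.
    x_loadings_ : ndarray (p, H)
        Loadings p_h = X^T t_h / (t_h^T t_h) from the deflated design.
    y_loadings_ : ndarray (H,)
        Score-regression coefficients q_h.
    coef_path_ : ndarray (p, H+1)
        Coefficients on the original column scale for 0..H retained
        components (column 0 is the null model).
    r2_path_ : ndarray (H+1,)
        Cumulative fraction of outcome variance explained.
    n_components_ : int
        Number of components actually extracted.
    """

    def __init__(self, n_components=2, scale=False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        if isinstance(X, DesignMatrix):
            self.design_columns_ = list(X.columns)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        if n < 2:
            raise ValueError("need at least 2 observations")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite entries")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        if yc @ yc <= 0:
            raise ValueError("y has zero variance")
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                raise ValueError("cannot scale zero-variance columns")
            self.x_std_ = sd
            Xc = Xc / sd
        else:
            self.x_std_ = np.ones(p)

        sv = np.linalg.svd(Xc, compute_uv=False)
        rank = int(np.sum(sv > max(n, p) * np.finfo(float).eps * sv[0])) if sv.size else 0
        self.rank_ = rank
        H = int(self.n_components)
        if H < 0:
            raise ValueError("n_components must be >= 0")
        if H > rank:
            logger.warning(
                "n_components=%d exceeds numerical rank %d; truncating", H, rank
            )
            H = rank

        W, T, P, q = _nipals_pls1(Xc, yc, H)
        self.x_weights_, self.x_scores_, self.x_loadings_, self.y_loadings_ = W, T, P, q
        self.n_components_ = W.shape[1]
        self.coef_path_ = _coef_path(W, P, q) / self.x_std_[:, None]
        ss_tot = yc @ yc
        # fitted at h components = sum_{j<=h} q_j t_j (scores are orthogonal)
        fitted = np.zeros((len(yc), self.n_components_ + 1))
        for h in range(1, self.n_components_ + 1):
            fitted[:, h] = fitted[:, h - 1] + q[h - 1] * T[:, h - 1]
        self.r2_path_ = 1.0 - ((yc[:, None] - fitted) ** 2).sum(axis=0) / ss_tot
        self.coef_ = self.coef_path_[:, self.n_components_]
        self.intercept_ = self.y_mean_ - self.x_mean_ @ self.coef_
        return self

    # ------------------------------------------------------------------
    def coefficients(self, h=None):
        """Coefficients and intercept on the original column scale.

        ``h = 0`` gives the null model (zero slopes, intercept = mean of y).
        Centering is undone through the intercept, scaling through division
        by the column standard deviations.
        """
        check_is_fitted(self, "coef_path_")
        if h is None:
            h = self.n_components_
        h = int(h)
        if not 0 <= h <= self.n_components_:
            raise ValueError(f"h must lie in [0, {self.n_components_}], got {h}")
        coef = self.coef_path_[:, h].copy()
        intercept = self.y_mean_ - self.x_mean_ @ coef
        return coef, intercept

    def predict(self, X, h=None):
        check_is_fitted(self, "coef_path_")
        if isinstance(X, DesignMatrix):
            if hasattr(self, "design_columns_"):
                got = [c.name for c in X.columns]
                expect = [c.name for c in self.design_columns_]
                if got != expect:
                    raise ValueError(
                        f"design columns {got} do not match fitted columns {expect}"
                    )
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.x_mean_.size:
            raise ValueError(
                f"X has {X.shape[1] if X.ndim == 2 else 'wrong'} columns, "
                f"expected {self.x_mean_.size}"
            )
        coef, intercept = self.coefficients(h)
        return intercept + X @ coef

    def explained_variance(self):
        """Cumulative R² per retained component count (index 0 = null model)."""
        check_is_fitted(self, "r2_path_")
        return self.r2_path_.copy()


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_pls1(X, y, n_components=2, scale=False) -> PLS1Regression:
    """Fit PLS1 and return the fitted estimator."""
    return PLS1Regression(n_components=n_components, scale=scale).fit(X, y)


def coefficients(fit: PLS1Regression, h=None):
    return fit.coefficients(h)


def predict(fit: PLS1Regression, X, h=None):
    return fit.predict(X, h=h)


def explained_variance(fit: PLS1Regression):
    return fit.explained_variance()
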