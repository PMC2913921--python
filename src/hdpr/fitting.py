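"""Zero-intercept slope estimation for unwrapped residual vs. mass.

The model is D_R = b * P_M with no intercept: an empty peptide has no mass and
no mass defect. Large reference sets are fit by exact least squares,

    b = sum(D_R * P_M) / sum(P_M^2),

minimizing the error sum of squares SSE = sum((D_R - b*P_M)^2). Small user mass
lists are irregular and outlier-prone, so they are fit by M-estimation: the
same weighted update is iterated with Huber weights (re-weighted least squares),
with the residual scale re-estimated each iteration from the median absolute
deviation about the origin-constrained line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

#: Huber tuning constant (in units of scale): 95% efficiency at the Gaussian.
HUBER_C = 1.345
#: Tukey bisquare tuning constant with the same efficiency.
BISQUARE_C = 4.685
#: MAD-to-sigma consistency factor for Gaussian residuals.
MAD_SCALE = 0.6744897501960817


@dataclass(frozen=True)
class SlopeFit:
    """A fitted zero-intercept slope with its uncertainty and fit diagnostics."""

    b: float
    se_b: float
    sse: float
    n: int
    method: str
    converged: bool = True
    n_iter: int = 0


def _validate(masses, residuals) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(masses, dtype=float)
    y = np.asarray(residuals, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("masses and residuals must be 1-D arrays of equal length")
    if x.size == 0:
        raise ValueError("at least one point is required")
    if np.any(x <= 0):
        raise ValueError("masses must be positive")
    return x, y


def fit_slope_ols(masses, unwrapped_residuals) -> SlopeFit:
    """Exact zero-intercept least squares: b = sum(y*x) / sum(x^2)."""
    x, y = _validate(masses, unwrapped_residuals)
    sxx = float(x @ x)
    b = float(x @ y) / sxx
    resid = y - b * x
    sse = float(resid @ resid)
    n = x.size
    se_b = math.sqrt(sse / (n - 1) / sxx) if n >= 2 else float("nan")
    return SlopeFit(b=b, se_b=se_b, sse=sse, n=n, method="ols_zero_intercept")


def _weights(u: np.ndarray, loss: str) -> np.ndarray:
    au = np.abs(u)
    if loss == "huber":
        with np.errstate(divide="ignore"):
            w = np.where(au > HUBER_C, HUBER_C / au, 1.0)
        return w
    if loss == "bisquare":
        w = np.zeros_like(u)
        inside = au < BISQUARE_C
        w[inside] = (1.0 - (u[inside] / BISQUARE_C) ** 2) ** 2
        return w
    raise ValueError(f"unknown robust loss {loss!r}")


def fit_slope_robust(
    masses,
    unwrapped_residuals,
    loss: str = "huber",
    max_iterations: int = 50,
    convergence_tol: float = 1e-8,
) -> SlopeFit:
    """Zero-intercept M-estimation by iteratively re-weighted least squares.

    Starts from the OLS slope; each iteration re-estimates the residual scale
    as MAD/0.6745 about the current line and re-solves the weighted
    zero-intercept normal equation. Sets with fewer than 3 points fall back to
    plain OLS with a warning. Non-convergence within ``max_iterations`` returns
    the last iterate flagged ``converged=False``.
    """
    x, y = _validate(masses, unwrapped_residuals)
    if x.size < 3:
        logger.warning("robust fit requested with n=%d < 3; falling back to OLS", x.size)
        return fit_slope_ols(x, y)

    b = fit_slope_ols(x, y).b
    w = np.ones_like(x)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        resid = y - b * x
        scale = float(np.median(np.abs(resid))) / MAD_SCALE
        if scale <= np.finfo(float).tiny ** 0.5:
            # (near-)exact fit for at least half the points: done
            w = np.ones_like(x)
            converged = True
            break
        w = _weights(resid / scale, loss)
        swx = float((w * x) @ x)
        if swx == 0.0:
            raise RuntimeError("all robust weights vanished")
        b_new = float((w * x) @ y) / swx
        if abs(b_new - b) <= convergence_tol * max(abs(b), np.finfo(float).tiny):
            b = b_new
            converged = True
            break
        b = b_new
    if not converged:
        logger.warning("robust fit did not converge in %d iterations", max_iterations)

    resid = y - b * x
    sse = float(resid @ resid)
    # standard error from the final weighted least-squares step
    swx = float((w * x) @ x)
    se_b = math.sqrt(float(w @ (resid * resid)) / (x.size - 1) / swx)
    return SlopeFit(
        b=b,
        se_b=se_b,
        sse=sse,
        n=x.size,
        method="robust_iwls",
        converged=converged,
        n_iter=n_iter,
    )


class ZeroInterceptRegressor(RegressorMixin, BaseEstimator):
    """Regression through the origin, optionally robust (Huber/bisquare IWLS).

    Parameters
    ----------
    method : {"ols", "huber", "bisquare"}, default "huber"
        "ols" is exact least squares; the others are M-estimators fit by
        iteratively re-weighted least squares.
    max_iterations : int, default 50
    convergence_tol : float, default 1e-8
        Relative slope change below which IWLS stops.

    Attributes
    ----------
    coef_ : ndarray of shape (1,) — the fitted slope b.
    se_ : float — standard error of b.
    slope_fit_ : SlopeFit — full fit record (SSE, n, convergence flag).
    """

    def __init__(
        self,
        method: str = "huber",
        max_iterations: int = 50,
        convergence_tol: float = 1e-8,
    ):
        self.method = method
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol

    @staticmethod
    def _as_column(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("expected a single-feature design (n, 1)")
        return X

    def fit(self, X, y):
        x = self._as_column(X)[:, 0]
        if self.method == "ols":
            fit = fit_slope_ols(x, y)
        elif self.method in ("huber", "bisquare"):
            fit = fit_slope_robust(
                x,
                y,
                loss=self.method,
                max_iterations=self.max_iterations,
                convergence_tol=self.convergence_tol,
            )
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.slope_fit_ = fit
        self.coef_ = np.array([fit.b])
        self.intercept_ = 0.0
        self.se_ = fit.se_b
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return self._as_column(X)[:, 0] * self.coef_[0]
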