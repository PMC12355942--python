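"""Model I (ordinary / robust) and model II (geometric mean) regression.

Estimators follow the scikit-learn protocol (``fit``/``predict``, fitted
attributes with trailing underscores, ``get_params``/``set_params``) so they
compose with sklearn pipelines and model selection.  The module-level
``ols_fit`` / ``gm_fit`` / ``fit_metrics`` helpers are thin wrappers.

Model I regression assumes an error-free predictor; the robust variant uses
iteratively reweighted least squares with Tukey's bisquare (tuning constant
4.685, MAD scale), the convention behind common statistical tooling.  Model
II (geometric-mean, also called reduced-major-axis) regression minimises
offsets along both axes equally and is appropriate when x and y both carry
measurement error — e.g. a cross-instrument compilation where neither SUVA
nor a fluorescence index can be treated as error-free.  Its slope is
sign(r) * s_y / s_x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FitResult",
    "ModelIRegression",
    "GeometricMeanRegression",
    "ols_fit",
    "gm_fit",
    "fit_metrics",
]


@dataclass
class FitResult:
    """Coefficients and diagnostics of a fitted straight line."""

    slope: float
    slope_se: float
    intercept: float | None  # None for through-origin fits
    intercept_se: float | None
    r_squared: float
    rmse: float  # sqrt(RSS / df), in y units
    n: int
    df: int
    residuals: np.ndarray
    method: str  # 'modelI' | 'modelI_robust' | 'modelII_geometric'
    weights: np.ndarray | None = field(default=None, repr=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        b0 = 0.0 if self.intercept is None else self.intercept
        return self.slope * np.asarray(x, dtype=float) + b0


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D (or a single-column 2-D array)")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


class ModelIRegression(BaseEstimator, RegressorMixin):
    """Ordinary or robust (IRLS bisquare) model I straight-line regression.

    Parameters
    ----------
    with_intercept : bool, default True
        Include an intercept; through-origin otherwise.
    robust : bool, default False
        Use iteratively reweighted least squares with Tukey's bisquare
        (c = 4.685) and MAD scale, converging when the maximum coefficient
        change drops below ``tol`` or after ``max_iter`` iterations.
    """

    def __init__(self, with_intercept: bool = True, robust: bool = False,
                 tol: float = 1e-8, max_iter: int = 50):
        self.with_intercept = with_intercept
        self.robust = robust
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        x = _as_1d(X, "X")
        y = _as_1d(y, "y")
        if x.size != y.size:
            raise ValueError("X and y must have equal length")
        n_coef = 2 if self.with_intercept else 1
        if x.size < n_coef + 1:
            raise ValueError(f"need at least {n_coef + 1} observations")
        if np.ptp(x) == 0:
            raise ValueError("X is constant; slope is not identifiable")

        design = sm.add_constant(x) if self.with_intercept else x[:, None]
        weights = None
        if self.robust:
            model = sm.RLM(y, design, M=sm.robust.norms.TukeyBiweight(c=4.685))
            res = model.fit(maxiter=self.max_iter, tol=self.tol, conv="coefs",
                            scale_est="mad")
            weights = np.asarray(res.weights)
            method = "modelI_robust"
        else:
            res = sm.OLS(y, design).fit()
            method = "modelI"

        params = np.atleast_1d(res.params)
        bse = np.atleast_1d(res.bse)
        if self.with_intercept:
            intercept, slope = float(params[0]), float(params[1])
            intercept_se, slope_se = float(bse[0]), float(bse[1])
        else:
            intercept = intercept_se = None
            slope, slope_se = float(params[0]), float(bse[0])

        resid = y - (slope * x + (intercept or 0.0))
        df = x.size - n_coef
        rss = float(np.sum(resid**2))
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        self.result_ = FitResult(slope, slope_se, intercept, intercept_se, r2,
                                 float(np.sqrt(rss / df)) if df > 0 else 0.0,
                                 int(x.size), int(df), resid, method, weights)
        self.coef_ = np.array([slope])
        self.intercept_ = 0.0 if intercept is None else intercept
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        return self.result_.predict(_as_1d(X, "X"))


class GeometricMeanRegression(BaseEstimator, RegressorMixin):
    """Model II geometric-mean (reduced-major-axis) regression.

    slope = sign(r) * s_y / s_x; intercept = mean(y) - slope * mean(x).
    The slope standard error uses the common approximation
    |slope| * sqrt((1 - r^2) / n).  r = 0 leaves the slope sign undefined
    and is an error.
    """

    def fit(self, X, y):
        x = _as_1d(X, "X")
        y = _as_1d(y, "y")
        if x.size != y.size:
            raise ValueError("X and y must have equal length")
        if x.size < 3:
            raise ValueError("need at least 3 observations")
        sx = float(np.std(x, ddof=1))
        sy = float(np.std(y, ddof=1))
        if sx == 0 or sy == 0:
            raise ValueError("zero variance in X or y")
        r = float(np.corrcoef(x, y)[0, 1])
        if r == 0:
            raise ValueError("correlation is zero; geometric-mean slope sign undefined")
        slope = float(np.sign(r)) * sy / sx
        intercept = float(np.mean(y) - slope * np.mean(x))
        n = x.size
        slope_se = abs(slope) * float(np.sqrt((1.0 - r**2) / n))
        intercept_se = slope_se * float(np.sqrt(np.mean(x**2)))
        resid = y - (slope * x + intercept)
        df = n - 2
        rss = float(np.sum(resid**2))
        tss = float(np.sum((y - y.mean()) ** 2))
        self.result_ = FitResult(slope, slope_se, intercept, intercept_se,
                                 r**2, float(np.sqrt(rss / df)) if df > 0 else 0.0,
                                 int(n), int(df), resid, "modelII_geometric")
        self.coef_ = np.array([slope])
        self.intercept_ = intercept
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        return self.result_.predict(_as_1d(X, "X"))


def ols_fit(x, y, with_intercept: bool = True, robust: bool = False) -> FitResult:
    """Model I least squares of y on x; robust switches to IRLS bisquare."""
    return ModelIRegression(with_intercept=with_intercept, robust=robust).fit(x, y).result_


def gm_fit(x, y) -> FitResult:
    """Model II geometric-mean regression of y on x."""
    return GeometricMeanRegression().fit(x, y).result_


def fit_metrics(observed, predicted, n_params: int) -> tuple[float, float]:
    """(R^2, RMSE) of predictions against observations.

    R^2 = 1 - RSS/TSS and may be negative when the predictions fit worse
    than the horizontal line at the observed mean.  RMSE uses
    df = n - n_params.
    """
    obs = _as_1d(observed, "observed")
    pred = _as_1d(predicted, "predicted")
    if obs.size != pred.size:
        raise ValueError("observed and predicted must have equal length")
    if obs.size <= n_params:
        raise ValueError("need n > n_params")
    resid = obs - pred
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero total sum of squares: observed values are constant")
    r2 = 1.0 - float(np.sum(resid**2)) / tss
    rmse = float(np.sqrt(np.sum(resid**2) / (obs.size - n_params)))
    return r2, rmse
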