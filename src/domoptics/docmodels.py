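"""DOC-prediction models from optical measurements, with multimodel inference.

The model family:

* **base** — DOC = beta0 + beta1 * A254: the prevailing proportionality
  between decadic absorbance at 254 nm (1/m) and DOC (mg/L) in
  terrestrially dominated waters.
* **arint** (aromaticity interaction) — DOC = b0 + b1*A254 + b2*A254*P,
  where P is an aromaticity proxy (ARIX, SUVA, or 1/S275-295 with S in
  1/um).  Aromaticity enters only through the interaction, never as a main
  effect: ARIX and S275-295 are undefined at zero absorbance, so a main
  effect could take on meaningless values.  b0 is uncolored DOC; cDOC =
  DOC - b0 is the colored fraction, and rearranging gives the
  Beer-Lambert-like form A254 = cDOC / (b1 + b2*P), so the molar
  absorptivity of colored DOC is proportional to 1 / (b1 + b2*P).
* **pan_arctic** — log10(DOC / a350) = C + M * S275-295, with a350 the
  Napierian absorption coefficient at 350 nm (1/m) and S in 1/um.
* **doc_uv / doc_ls** — DOC[uM] = Phi * a275 * (S275-295 + 0.078*S380-443
  - 0.0084) + DOC_cor with slopes in 1/nm; the global DOC_UV preset fixes
  Phi = 1507 m*nm*umol/L and DOC_cor = 32.2 umol/L (zero estimated
  parameters), while DOC_LS least-squares fits both locally.

Model comparison balances Gaussian log-likelihood against parsimony using
AIC, AICc, BIC and CAIC with the estimated-parameter counts 2 (base,
pan_arctic, doc_ls), 3 (arint) and 0 (doc_uv preset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .io import SampleTable
from .regression import fit_metrics

__all__ = [
    "CARBON_MOLAR_MASS",
    "ARINTRegressor",
    "BaseDOCRegressor",
    "PanArcticRegressor",
    "YanDOCModel",
    "ICSet",
    "DOCDiagnostics",
    "fit_doc_model",
    "predict_doc",
    "invert_a254",
    "diagnostics",
    "info_criteria",
    "compare_doc_models",
]

CARBON_MOLAR_MASS = 12.011  # g/mol; converts umol C/L to mg C/L via *12.011/1000

#: aromaticity proxies accepted by the ARINT model, with the unit of b2
ARINT_PROXIES = {
    "arix": "g m^-2",
    "suva": "g^2 m^-4",
    "inv_s275_295": "Mg m^-1",  # P = 1/S with S in 1/um
}


def _check_design(X, n_cols: int, names: str) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != n_cols:
        raise ValueError(f"X must be 2-D with columns [{names}]")
    if not np.all(np.isfinite(arr)):
        raise ValueError("X contains non-finite values")
    return arr


class ARINTRegressor(BaseEstimator, RegressorMixin):
    """Aromaticity-interaction model DOC = b0 + b1*A254 + b2*A254*P.

    ``fit`` expects ``X`` with columns ``[A254, P]`` (A254 decadic 1/m, P in
    the proxy's units) and ``y`` = DOC (mg/L).  The fitted proxy kind is
    recorded and predictions with another proxy are refused at the table
    level.  Fitted attributes: ``b0_``, ``b1_``, ``b2_`` and their standard
    errors ``b0_se_``, ``b1_se_``, ``b2_se_``.
    """

    n_estimated_params = 3  # b0, b1, b2 (residual variance excluded by convention)

    def __init__(self, proxy_kind: str = "arix"):
        self.proxy_kind = proxy_kind

    def fit(self, X, y):
        if self.proxy_kind not in ARINT_PROXIES:
            raise ValueError(f"unknown proxy kind {self.proxy_kind!r}; "
                             f"expected one of {sorted(ARINT_PROXIES)}")
        X = _check_design(X, 2, "A254, P")
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 4:
            raise ValueError("ARINT needs n >= 4")
        a254, proxy = X[:, 0], X[:, 1]
        design = np.column_stack([np.ones_like(a254), a254, a254 * proxy])
        if np.linalg.matrix_rank(design) < 3:
            raise ValueError(
                "rank-deficient design: A254 and A254*P are collinear "
                "(constant proxy?)"
            )
        res = sm.OLS(y, design).fit()
        self.b0_, self.b1_, self.b2_ = (float(v) for v in res.params)
        self.b0_se_, self.b1_se_, self.b2_se_ = (float(v) for v in res.bse)
        self.coef_ = np.array([self.b1_, self.b2_])
        self.intercept_ = self.b0_
        self.residuals_ = y - res.fittedvalues
        self.n_ = int(y.size)
        self.r_squared_, self.rmse_ = fit_metrics(y, np.asarray(res.fittedvalues),
                                                  self.n_estimated_params)
        self.b2_unit_ = ARINT_PROXIES[self.proxy_kind]
        return self

    def predict(self, X):
        check_is_fitted(self, "b0_")
        X = _check_design(X, 2, "A254, P")
        return self.b0_ + X[:, 0] * (self.b1_ + self.b2_ * X[:, 1])


class BaseDOCRegressor(BaseEstimator, RegressorMixin):
    """Base model DOC = beta0 + beta1 * A254 (no aromaticity term)."""

    n_estimated_params = 2

    def fit(self, X, y):
        X = _check_design(np.asarray(X, dtype=float).reshape(-1, 1), 1, "A254")
        y = np.asarray(y, dtype=float)
        res = sm.OLS(y, sm.add_constant(X[:, 0])).fit()
        self.intercept_, self.slope_ = (float(v) for v in res.params)
        self.intercept_se_, self.slope_se_ = (float(v) for v in res.bse)
        self.coef_ = np.array([self.slope_])
        self.residuals_ = y - res.fittedvalues
        self.n_ = int(y.size)
        self.r_squared_, self.rmse_ = fit_metrics(y, np.asarray(res.fittedvalues),
                                                  self.n_estimated_params)
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x


class PanArcticRegressor(BaseEstimator, RegressorMixin):
    """Pan-Arctic model log10(DOC/a350) = C + M * S275-295.

    ``X`` columns: ``[a350, S275_295]`` with a350 Napierian (1/m) and S in
    1/um (the convention under which the published M range 0.04-0.07 with
    S around 15-25 makes sense); ``y`` = DOC in the table's units (mg/L).
    C and M are fitted by OLS in log10 space.
    """

    n_estimated_params = 2

    def fit(self, X, y):
        X = _check_design(X, 2, "a350, S275_295[1/um]")
        y = np.asarray(y, dtype=float)
        ratio = y / X[:, 0]
        if np.any(~np.isfinite(ratio)) or np.any(ratio <= 0):
            raise ValueError("DOC / a350 must be positive and finite for the log10 fit")
        res = sm.OLS(np.log10(ratio), sm.add_constant(X[:, 1])).fit()
        self.C_, self.M_ = (float(v) for v in res.params)
        self.C_se_, self.M_se_ = (float(v) for v in res.bse)
        pred = self.predict(X)
        self.residuals_ = y - pred
        self.n_ = int(y.size)
        self.r_squared_, self.rmse_ = fit_metrics(y, pred, self.n_estimated_params)
        return self

    def predict(self, X):
        check_is_fitted(self, "C_")
        X = _check_design(X, 2, "a350, S275_295[1/um]")
        return X[:, 0] * 10.0 ** (self.C_ + self.M_ * X[:, 1])


class YanDOCModel(BaseEstimator, RegressorMixin):
    """DOC from a275 and two spectral slopes (global DOC_UV or local DOC_LS).

    DOC[uM] = Phi * a275 * (S275-295 + 0.078 * S380-443 - 0.0084) + DOC_cor,
    slopes in 1/nm, a275 Napierian (1/m).  With ``phi``/``doc_cor`` given at
    construction the model is the fixed global preset (DOC_UV; zero
    estimated parameters).  ``fit`` least-squares estimates both locally
    (DOC_LS).  ``predict`` returns mg/L (uM * 12.011 / 1000).
    """

    #: fixed nm-domain constants of the slope combination
    S380_WEIGHT = 0.078
    OFFSET = 0.0084
    GLOBAL_PHI = 1507.0  # m nm umol/L
    GLOBAL_DOC_COR = 32.2  # umol/L

    def __init__(self, phi: float | None = None, doc_cor: float | None = None):
        self.phi = phi
        self.doc_cor = doc_cor

    @classmethod
    def global_uv(cls) -> "YanDOCModel":
        """The global DOC_UV preset (Phi = 1507, DOC_cor = 32.2)."""
        return cls(phi=cls.GLOBAL_PHI, doc_cor=cls.GLOBAL_DOC_COR)

    @property
    def is_preset(self) -> bool:
        return self.phi is not None and self.doc_cor is not None

    @property
    def n_estimated_params(self) -> int:
        return 0 if self.is_preset else 2

    def _slope_term(self, X) -> np.ndarray:
        X = _check_design(X, 3, "a275, S275_295[1/nm], S380_443[1/nm]")
        return X[:, 0] * (X[:, 1] + self.S380_WEIGHT * X[:, 2] - self.OFFSET)

    def fit(self, X, y):
        """Fit Phi and DOC_cor by least squares; y is DOC in mg/L."""
        y_um = np.asarray(y, dtype=float) * 1000.0 / CARBON_MOLAR_MASS
        term = self._slope_term(X)
        if self.is_preset:
            self.phi_, self.doc_cor_ = float(self.phi), float(self.doc_cor)
            self.phi_se_ = self.doc_cor_se_ = 0.0
        else:
            res = sm.OLS(y_um, sm.add_constant(term)).fit()
            self.doc_cor_, self.phi_ = (float(v) for v in res.params)
            self.doc_cor_se_, self.phi_se_ = (float(v) for v in res.bse)
        pred = self.predict(X)
        y_mg = np.asarray(y, dtype=float)
        self.residuals_ = y_mg - pred
        self.n_ = int(y_mg.size)
        self.r_squared_, self.rmse_ = fit_metrics(
            y_mg, pred, max(self.n_estimated_params, 0))
        return self

    def predict(self, X):
        if not hasattr(self, "phi_"):
            if not self.is_preset:
                raise ValueError("DOC_LS model must be fitted before predicting "
                                 "(or construct the global_uv preset)")
            self.phi_, self.doc_cor_ = float(self.phi), float(self.doc_cor)
        doc_um = self.phi_ * self._slope_term(X) + self.doc_cor_
        return doc_um * CARBON_MOLAR_MASS / 1000.0


@dataclass
class ICSet:
    """Gaussian-likelihood information criteria for one fitted model."""

    logL: float
    k: int
    n: int
    aic: float
    aicc: float
    bic: float
    caic: float


@dataclass
class DOCDiagnostics:
    """Per-sample ARINT diagnostics.

    ``cdoc`` is colored DOC (DOC - b0, g/m^3); ``epsilon_proxy`` is the
    relative molar absorptivity 1/(b1 + b2*P) (NaN where the denominator is
    non-positive, with ids in ``epsilon_undefined``); ``interaction_ratio``
    is b2*P/b1, whose spread across a data set measures how much aromaticity
    modulates the DOC-absorbance proportionality.
    """

    cdoc: pd.Series
    epsilon_proxy: pd.Series
    interaction_ratio: pd.Series
    epsilon_undefined: list = field(default_factory=list)

    @property
    def ratio_range(self) -> tuple[float, float]:
        return float(self.interaction_ratio.min()), float(self.interaction_ratio.max())


def info_criteria(residuals, k: int, n: int | None = None) -> ICSet:
    """AIC, AICc, BIC and CAIC from residuals of a Gaussian model.

    logL = -(n/2) * (ln 2pi + ln(RSS/n) + 1); k counts estimated mean
    parameters only (0 for the DOC_UV preset, 2 for base/pan_arctic/doc_ls,
    3 for ARINT).  ``include_variance_param`` on :func:`compare_doc_models`
    can add one uniformly without changing the ranking.
    """
    resid = np.asarray(residuals, dtype=float)
    if n is None:
        n = resid.size
    if n != resid.size:
        raise ValueError("n must equal the number of residuals")
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    rss = float(np.sum(resid**2))
    if rss <= 0:
        raise ValueError(
            "zero residual sum of squares: the Gaussian likelihood diverges; "
            "report the comparison as degenerate (perfect fit)"
        )
    logL = -0.5 * n * (math.log(2.0 * math.pi) + math.log(rss / n) + 1.0)
    aic = -2.0 * logL + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    bic = -2.0 * logL + k * math.log(n)
    caic = -2.0 * logL + k * (math.log(n) + 1.0)
    return ICSet(logL, int(k), int(n), aic, aicc, bic, caic)


def _table_columns(table: SampleTable, cols: list[str]) -> pd.DataFrame:
    missing = [c for c in cols if c not in table.df.columns]
    if missing:
        raise ValueError(f"sample table lacks required columns {missing}")
    return table.df[cols].astype(float)


def _proxy_values(df: pd.DataFrame, proxy: str) -> pd.Series:
    if proxy == "arix":
        return df["arix"]
    if proxy == "suva":
        return df["suva"] if "suva" in df else df["a254"] / df["doc"]
    if proxy == "inv_s275_295":
        return 1.0 / (1000.0 * df["s275_295"])  # table stores S in 1/nm; P = 1/S[1/um]
    raise ValueError(f"unknown ARINT proxy {proxy!r}")


_PROXY_SOURCE_COLUMNS = {"arix": ["arix"], "suva": ["a254", "doc"],
                         "inv_s275_295": ["s275_295"]}


def fit_doc_model(model_id: str, table: SampleTable, proxy: str | None = None):
    """Fit one DOC model on a sample table; returns the fitted estimator.

    ``model_id`` is one of ``base``, ``arint`` (requires ``proxy``),
    ``pan_arctic``, ``doc_ls``; the unfittable ``doc_uv`` preset is obtained
    from :meth:`YanDOCModel.global_uv`.
    """
    if model_id == "base":
        df = _table_columns(table, ["a254", "doc"]).dropna()
        return BaseDOCRegressor().fit(df[["a254"]].values, df["doc"].values)
    if model_id == "arint":
        if proxy is None:
            raise ValueError("ARINT requires a proxy kind (arix, suva or inv_s275_295)")
        cols = ["a254", "doc"] + [c for c in _PROXY_SOURCE_COLUMNS[proxy]
                                  if c not in ("a254", "doc")]
        df = _table_columns(table, cols).dropna()
        X = np.column_stack([df["a254"].values, _proxy_values(df, proxy).values])
        return ARINTRegressor(proxy_kind=proxy).fit(X, df["doc"].values)
    if model_id == "pan_arctic":
        df = _table_columns(table, ["a350", "s275_295", "doc"]).dropna()
        X = np.column_stack([df["a350"].values, 1000.0 * df["s275_295"].values])
        return PanArcticRegressor().fit(X, df["doc"].values)
    if model_id in ("doc_ls", "doc_uv"):
        df = _table_columns(table, ["a275", "s275_295", "s380_443", "doc"]).dropna()
        X = df[["a275", "s275_295", "s380_443"]].values
        model = YanDOCModel.global_uv() if model_id == "doc_uv" else YanDOCModel()
        return model.fit(X, df["doc"].values)
    raise ValueError(f"unknown DOC model {model_id!r}")


def predict_doc(model, table: SampleTable) -> pd.Series:
    """Per-sample DOC predictions (mg/L) from a fitted model and a table."""
    df = table.df
    if isinstance(model, BaseDOCRegressor):
        pred = model.predict(df["a254"].astype(float).values)
    elif isinstance(model, ARINTRegressor):
        proxy = _proxy_values(df, model.proxy_kind)
        pred = model.predict(np.column_stack([df["a254"].astype(float).values,
                                              proxy.astype(float).values]))
    elif isinstance(model, PanArcticRegressor):
        pred = model.predict(np.column_stack([df["a350"].astype(float).values,
                                              1000.0 * df["s275_295"].astype(float).values]))
    elif isinstance(model, YanDOCModel):
        pred = model.predict(df[["a275", "s275_295", "s380_443"]].astype(float).values)
    else:
        raise TypeError(f"unknown DOC model type {type(model).__name__}")
    return pd.Series(pred, index=df.index, name="doc_predicted")


def invert_a254(fit: ARINTRegressor, doc, proxy) -> np.ndarray:
    """Predicted A254 from DOC and the proxy: A254 = (DOC - b0) / (b1 + b2*P).

    Round-trips with :meth:`ARINTRegressor.predict` to machine precision.
    Negative output (DOC below the uncolored intercept b0) is returned
    as-is; it flags a physically impossible combination.
    """
    check_is_fitted(fit, "b0_")
    doc = np.asarray(doc, dtype=float)
    proxy = np.asarray(proxy, dtype=float)
    return (doc - fit.b0_) / (fit.b1_ + fit.b2_ * proxy)


def diagnostics(fit: ARINTRegressor, table: SampleTable) -> DOCDiagnostics:
    """Colored DOC, relative molar absorptivity and interaction ratio per sample."""
    check_is_fitted(fit, "b0_")
    df = table.df
    proxy = _proxy_values(df, fit.proxy_kind).astype(float)
    cdoc = df["doc"].astype(float) - fit.b0_
    denom = fit.b1_ + fit.b2_ * proxy
    eps = pd.Series(np.where(denom > 0, 1.0 / denom, np.nan), index=df.index)
    undefined = df.loc[denom <= 0, "sample_id"].tolist()
    ratio = fit.b2_ * proxy / fit.b1_
    return DOCDiagnostics(cdoc.rename("cdoc"), eps.rename("epsilon_proxy"),
                          ratio.rename("interaction_ratio"), undefined)


def compare_doc_models(table: SampleTable, proxies: tuple[str, ...] = ("arix",),
                       include_variance_param: bool = False) -> pd.DataFrame:
    """Fit all applicable DOC models on shared complete cases and rank them.

    Returns a DataFrame (one row per model) with coefficients of
    determination, RMSE, the percent change in RMSE relative to the base
    model, the four information criteria, and a ``preferred`` flag on the
    model that is lowest on a majority of criteria (ties share the flag).
    """
    df = table.df
    needed = {"base": ["a254", "doc"]}
    for p in proxies:
        needed[f"arint_{p}"] = sorted(set(["a254", "doc"] + _PROXY_SOURCE_COLUMNS[p]))
    if {"a350", "s275_295"}.issubset(df.columns):
        needed["pan_arctic"] = ["a350", "s275_295", "doc"]
    if {"a275", "s275_295", "s380_443"}.issubset(df.columns):
        needed["doc_uv"] = ["a275", "s275_295", "s380_443", "doc"]
        needed["doc_ls"] = ["a275", "s275_295", "s380_443", "doc"]
    if len(needed) < 2:
        raise ValueError("fewer than two fittable models for this table")

    all_cols = sorted({c for cols in needed.values() for c in cols})
    present = [c for c in all_cols if c in df.columns]
    complete = df.dropna(subset=present)
    sub = SampleTable(complete.reset_index(drop=True), provenance=table.provenance)

    rows = []
    base_rmse = None
    for model_id in needed:
        if model_id.startswith("arint_"):
            fitted = fit_doc_model("arint", sub, proxy=model_id.split("_", 1)[1])
        else:
            fitted = fit_doc_model(model_id, sub)
        k = fitted.n_estimated_params + (1 if include_variance_param else 0)
        ics = info_criteria(fitted.residuals_, k, fitted.n_)
        row = {"model": model_id, "n": fitted.n_, "k": k,
               "r_squared": fitted.r_squared_, "rmse": fitted.rmse_,
               "logL": ics.logL, "aic": ics.aic, "aicc": ics.aicc,
               "bic": ics.bic, "caic": ics.caic}
        if model_id == "base":
            base_rmse = row["rmse"]
        rows.append(row)
    report = pd.DataFrame(rows)
    report["rmse_pct_change_vs_base"] = 100.0 * (report["rmse"] - base_rmse) / base_rmse

    criteria = ["aic", "aicc", "bic", "caic"]
    wins = pd.Series(0, index=report.index)
    for c in criteria:
        wins[report[c].idxmin()] += 1
    best = wins.max()
    report["criteria_won"] = wins
    report["preferred"] = (wins == best) & (wins >= len(criteria) / 2.0)
    return report.set_index("model")
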