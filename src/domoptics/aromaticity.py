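"""Published proxy equations linking optical indices to DOM aromaticity.

The registry holds the published calibrations exactly as printed:

* ``pa_pp_from_parix``:   %(PA+PP)            = 30.28 * PARIX
* ``hs_bb_from_arix``:    HS/BB               = 6.1 * ARIX
* ``suva_from_arix``:     SUVA                = 6.1 * ARIX - 0.7   (bulk waters, model II)
* ``suva_from_arix_isolates``: SUVA           = 4.5 * ARIX         (XAD isolates, through origin)
* ``aromaticity_from_suva``:   percent aromaticity = 6.52 * SUVA + 3.63  (13C-NMR calibration)
* ``aromaticity_from_arix``:   percent aromaticity = 29.3 * ARIX + 3.63

%(PA+PP) is the relative abundance of polycyclic aromatic (modified
aromaticity index > 0.66) plus polyphenolic (0.5-0.66) molecular formulas
from FT-ICR MS; HS/BB is the LC-OCD humic-substances to building-blocks
ratio.  The percent-aromaticity forms assume that the fluorescence of the
13C-NMR-characterised XAD isolates behaves like the isolate calibration
(slope 4.5); composing 6.52 * 4.5 = 29.34 rounds to the printed 29.3.

``fit_suva_model`` calibrates SUVA against an index locally, via model I
(optionally robust) or model II regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from types import MappingProxyType

from .io import SampleTable
from .regression import FitResult, GeometricMeanRegression, ModelIRegression

__all__ = [
    "PublishedModel",
    "PUBLISHED_MODELS",
    "apply_published_model",
    "invert_published_model",
    "fit_suva_model",
    "SUVACalibration",
]


@dataclass(frozen=True)
class PublishedModel:
    """An affine published calibration output = slope * input + intercept."""

    model_id: str
    input_kind: str  # 'ARIX' | 'PARIX' | 'SUVA'
    output_kind: str
    slope: float
    intercept: float
    caveat: str = ""

    def __call__(self, x: float) -> float:
        return self.slope * x + self.intercept


PUBLISHED_MODELS = MappingProxyType({
    m.model_id: m
    for m in (
        PublishedModel("pa_pp_from_parix", "PARIX", "%(PA+PP)", 30.28, 0.0,
                       "no intercept: zero long-emission fluorescence implies no "
                       "polycyclic-aromatic or polyphenolic formulas"),
        PublishedModel("hs_bb_from_arix", "ARIX", "HS/BB", 6.1, 0.0),
        PublishedModel("suva_from_arix", "ARIX", "SUVA", 6.1, -0.7,
                       "bulk-water model II calibration; negative output below "
                       "ARIX ~0.115 signals out-of-domain input (observed ARIX "
                       "range 0.15-1.1)"),
        PublishedModel("suva_from_arix_isolates", "ARIX", "SUVA", 4.5, 0.0,
                       "through-origin calibration on DOM isolates"),
        PublishedModel("aromaticity_from_suva", "SUVA", "percent aromaticity",
                       6.52, 3.63, "13C-NMR calibration on XAD-8 isolates"),
        PublishedModel("aromaticity_from_arix", "ARIX", "percent aromaticity",
                       29.3, 3.63,
                       "assumes isolate-like fluorescence; rough estimate "
                       "percent aromaticity ~ 30 x ARIX"),
    )
})


def apply_published_model(model_id: str, x: float) -> float:
    """Evaluate a registry calibration at ``x`` (index value >= 0).

    A negative prediction (possible for ``suva_from_arix`` at ARIX < 0.115)
    is returned with a warning rather than clamped: it flags input outside
    the calibration's observed domain.
    """
    if model_id not in PUBLISHED_MODELS:
        raise KeyError(f"unknown published model {model_id!r}; "
                       f"known: {sorted(PUBLISHED_MODELS)}")
    if x < 0:
        raise ValueError(f"{PUBLISHED_MODELS[model_id].input_kind} must be non-negative")
    y = PUBLISHED_MODELS[model_id](x)
    if y < 0:
        warnings.warn(
            f"{model_id} predicts a negative {PUBLISHED_MODELS[model_id].output_kind} "
            f"({y:.3g}) at input {x:.3g}: outside the calibration domain",
            stacklevel=2,
        )
    return y


def invert_published_model(model_id: str, y: float) -> float:
    """Solve a registry calibration for its input (requires nonzero slope)."""
    model = PUBLISHED_MODELS[model_id]
    return (y - model.intercept) / model.slope


class SUVACalibration(ModelIRegression):
    """Local calibration of SUVA on a fluorescence index, sklearn-style.

    ``method='modelII'`` switches to geometric-mean regression (appropriate
    when index and SUVA both carry instrument error, e.g. multi-instrument
    compilations); the robust flag applies to model I only.
    """

    def __init__(self, robust: bool = False, method: str = "modelI"):
        super().__init__(with_intercept=True, robust=robust)
        self.method = method

    def fit(self, X, y):
        if self.method == "modelII":
            if self.robust:
                raise ValueError("robust fitting applies to model I only")
            gm = GeometricMeanRegression().fit(X, y)
            self.result_ = gm.result_
            self.coef_ = gm.coef_
            self.intercept_ = gm.intercept_
            return self
        if self.method != "modelI":
            raise ValueError(f"unknown method {self.method!r}; expected modelI or modelII")
        return super().fit(X, y)


def fit_suva_model(table: SampleTable, index_name: str = "arix",
                   robust: bool = False, method: str = "modelI") -> FitResult:
    """Fit SUVA = beta1 * index + beta0 on a sample table.

    Rows missing the index or the ingredients of SUVA are dropped; the ids
    of dropped samples are attached to the result as ``dropped_samples``.
    """
    df = table.df
    if index_name not in df.columns:
        raise ValueError(f"table has no {index_name!r} column")
    suva = table.suva()
    x = df[index_name].astype(float)
    ok = x.notna() & suva.notna()
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 complete records; have {int(ok.sum())}")
    est = SUVACalibration(robust=robust, method=method)
    est.fit(x[ok].values, suva[ok].values)
    result = est.result_
    result.dropped_samples = df.loc[~ok, "sample_id"].tolist()  # type: ignore[attr-defined]
    return result
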