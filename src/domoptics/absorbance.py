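"""CDOM absorbance quantities: A254, Napierian coefficients, spectral slopes, SUVA.

Conventions
-----------
Decadic absorbance ``A`` is the raw, dimensionless spectrophotometer reading
for the cell in use.  ``A254`` in sample tables is decadic absorbance per
meter (A in a 1 cm cell times 100).  Napierian absorption coefficients are
``a(lambda) = ln(10) * A(lambda) / path_length_m`` (1/m).  Spectral slopes S
are stored in 1/nm; the micrometer view is 1000x that value.  Conversions
between the two S conventions happen explicitly at model boundaries, never
implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io import AbsorbanceSpectrum

__all__ = [
    "SlopeFit",
    "SlopeFitError",
    "absorbance_at",
    "napierian_coefficient",
    "spectral_slope",
    "compute_suva",
    "LN10",
]

LN10 = math.log(10.0)


class SlopeFitError(ValueError):
    """Raised when a spectral slope cannot be fitted; may carry a loglinear fallback."""

    def __init__(self, message: str, fallback: "SlopeFit | None" = None):
        super().__init__(message)
        self.fallback = fallback


@dataclass
class SlopeFit:
    """An exponential CDOM slope fit a(lambda) = a_ref * exp(S * (lambda_ref - lambda)).

    ``S`` is in 1/nm (positive for the normal decay of CDOM absorption with
    wavelength); ``reference_wavelength`` is the upper band edge and
    ``amplitude`` the fitted Napierian coefficient there.
    """

    S: float  # 1/nm
    band: tuple[float, float]
    method: str  # 'loglinear' | 'nonlinear'
    reference_wavelength: float
    amplitude: float  # Napierian 1/m at the reference wavelength
    r_squared: float
    rmse: float

    @property
    def S_per_um(self) -> float:
        """The slope expressed in 1/micrometer (1000x the 1/nm value)."""
        return 1000.0 * self.S


def absorbance_at(spec: AbsorbanceSpectrum, wavelength: float) -> float:
    """Linearly interpolated decadic absorbance; exact on grid points."""
    wl = spec.wavelength
    if not (wl[0] <= wavelength <= wl[-1]):
        raise ValueError(f"wavelength {wavelength} nm outside grid [{wl[0]}, {wl[-1]}]")
    return float(np.interp(wavelength, wl, spec.absorbance))


def napierian_coefficient(spec: AbsorbanceSpectrum, wavelength: float) -> float:
    """Napierian absorption coefficient a(lambda) = ln(10) * A(lambda) / l (1/m)."""
    return LN10 * absorbance_at(spec, wavelength) / spec.path_length


def decadic_per_meter(spec: AbsorbanceSpectrum, wavelength: float) -> float:
    """Decadic absorbance per meter, e.g. the A254 convention of SUVA."""
    return absorbance_at(spec, wavelength) / spec.path_length


def spectral_slope(spec: AbsorbanceSpectrum, band: tuple[float, float],
                   method: str = "loglinear") -> SlopeFit:
    """Fit the exponential decay rate S over ``band`` (nm).

    ``loglinear`` regresses ln a(lambda) on lambda (S = -slope).
    ``nonlinear`` least-squares fits a(lambda) = a_ref * exp(S*(lambda_ref -
    lambda)) with lambda_ref the band's upper edge, initialised from the
    loglinear estimate.  Both agree exactly on noise-free exponential
    spectra; on noisy data they weight residuals differently.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    wl = spec.wavelength
    sel = (wl >= lo) & (wl <= hi)
    lam = wl[sel]
    a = LN10 * spec.absorbance[sel] / spec.path_length  # Napierian, 1/m
    if lam.size < 5:
        raise SlopeFitError(f"need >= 5 grid points in band {band}; have {lam.size}")
    if method not in ("loglinear", "nonlinear"):
        raise ValueError(f"unknown slope method {method!r}")
    if np.any(a <= 0):
        raise SlopeFitError(f"non-positive absorbance inside band {band}")

    # loglinear fit, also the nonlinear initialisation
    coeffs = np.polyfit(lam, np.log(a), 1)
    S_ll = -coeffs[0]
    amp_ll = math.exp(coeffs[1] - S_ll * hi)  # a at lambda_ref = hi

    def _finish(S: float, amp: float, meth: str) -> SlopeFit:
        pred = amp * np.exp(S * (hi - lam))
        resid = a - pred
        tss = float(np.sum((a - a.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
        rmse = float(np.sqrt(np.mean(resid**2)))
        return SlopeFit(float(S), (float(lo), float(hi)), meth, float(hi), float(amp), r2, rmse)

    if method == "loglinear":
        return _finish(S_ll, amp_ll, "loglinear")

    loglinear_fit = _finish(S_ll, amp_ll, "loglinear")
    try:
        popt, _ = curve_fit(
            lambda x, amp, S: amp * np.exp(S * (hi - x)), lam, a,
            p0=[amp_ll, S_ll], maxfev=10000,
        )
    except RuntimeError as exc:
        raise SlopeFitError(f"nonlinear slope fit failed to converge in band {band}",
                            fallback=loglinear_fit) from exc
    return _finish(popt[1], popt[0], "nonlinear")


def compute_suva(a254: float, doc: float) -> float:
    """SUVA (m^2/g C) = decadic A254 per meter divided by DOC (mg/L).

    The unit m^2/g C is equivalent to L/(mg C * m).  Typical natural waters
    with low dissolved iron fall in 1-6 m^2/g C.
    """
    if doc <= 0:
        raise ValueError("DOC must be positive to compute SUVA")
    if a254 < 0:
        raise ValueError("A254 must be non-negative")
    return a254 / doc
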