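"""Synthetic EEMs, CDOM absorbance spectra and DOC tables with known ground truth.

The generator exists so every estimator in the package can be exercised
against a closed-form truth without external data:

* **EEMs** are sums of separable Gaussian(excitation) x Gaussian(emission)
  fluorophores.  Real DOM emission is not separable; the form is chosen
  because every fluorescence index then has a closed form, which the truth
  object carries.  The default two-component palette — a long-emission
  humic-like component peaking above 500 nm and a short-emission component
  near 400 nm — spans ARIX ~0.15-1.1, the range observed in natural bulk
  waters.
* **Absorbance spectra** follow the exponential CDOM model
  a(lambda) = a_ref * exp(S * (lambda_ref - lambda)) (Napierian), stored as
  decadic cell absorbance for a given path length.
* **Sample tables** realise the colored/uncolored DOC split behind the
  aromaticity-interaction model: DOC = b0 + cDOC and
  A254 = cDOC / (b1 + b2 * P), so that DOC = b0 + b1*A254 + b2*A254*P holds
  exactly before noise.  The default regime (b0 = 1 g/m^3, b1 = 0.6 g/m^2,
  b2 = -0.3 g/m^2, proxy uniform on [0.2, 1.0], cDOC uniform on [2, 30])
  keeps b1 + b2*P positive, puts the interaction ratio b2*P/b1 in
  [-0.5, -0.1] and yields SUVA roughly in the 1-6 m^2/g C span of natural
  waters.

All randomness uses ``numpy.random.default_rng`` (PCG64) under an explicit
seed, so outputs are reproducible across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .absorbance import LN10
from .io import EEM, AbsorbanceSpectrum, SampleTable
from .sensitivity import NoiseModel, NoiseSpec

__all__ = [
    "FluorComponent",
    "SyntheticTruth",
    "DEFAULT_COMPONENTS",
    "NO_NOISE",
    "synth_eem",
    "synth_absorbance",
    "synth_dataset",
]


@dataclass(frozen=True)
class FluorComponent:
    """A separable Gaussian fluorophore profile."""

    amplitude: float
    ex_mean: float
    ex_sd: float
    em_mean: float
    em_sd: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.ex_sd <= 0 or self.em_sd <= 0:
            raise ValueError("component sds must be positive")

    def intensity(self, ex, em):
        """Closed-form intensity at (ex, em); broadcasts over arrays."""
        ex = np.asarray(ex, dtype=float)
        em = np.asarray(em, dtype=float)
        return (self.amplitude
                * np.exp(-((ex - self.ex_mean) ** 2) / (2.0 * self.ex_sd**2))
                * np.exp(-((em - self.em_mean) ** 2) / (2.0 * self.em_sd**2)))


#: long-emission (humic-like, peak > 500 nm) and short-emission (~400 nm) pair
DEFAULT_COMPONENTS = (
    FluorComponent(amplitude=1.0, ex_mean=340.0, ex_sd=80.0, em_mean=510.0, em_sd=60.0),
    FluorComponent(amplitude=1.0, ex_mean=310.0, ex_sd=70.0, em_mean=400.0, em_sd=40.0),
)

NO_NOISE = NoiseModel(doc=NoiseSpec("absolute", 0.0),
                      arix=NoiseSpec("absolute", 0.0),
                      a254=NoiseSpec("absolute", 0.0))


@dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic artefact, for parameter-recovery tests."""

    seed: int | None = None
    components: tuple[FluorComponent, ...] = ()
    cdom_slope: float | None = None  # 1/nm
    cdom_amplitude: float | None = None  # Napierian 1/m at the reference wavelength
    arint_coefficients: tuple[float, float, float] | None = None  # (b0, b1, b2)
    proxy_kind: str | None = None
    per_sample: pd.DataFrame | None = None
    noise: NoiseModel | None = None
    extras: dict = field(default_factory=dict)

    def true_intensity(self, ex, em):
        """Closed-form noise-free EEM intensity (sum over components)."""
        total = 0.0
        for comp in self.components:
            total = total + comp.intensity(ex, em)
        return total

    def true_arix(self) -> float:
        """Closed-form ARIX = I(320, 520) / I(320, 390) of the component sum."""
        return float(self.true_intensity(320.0, 520.0) / self.true_intensity(320.0, 390.0))


_INDEX_REQUIREMENTS = {
    "arix": (320.0, 320.0, 390.0, 520.0),
    "fi": (370.0, 370.0, 470.0, 520.0),
    "hix": (254.0, 254.0, 300.0, 480.0),
    "bix": (310.0, 310.0, 380.0, 435.0),
}


def synth_eem(components=DEFAULT_COMPONENTS,
              ex_grid=None, em_grid=None,
              noise_sd: float = 0.0, seed: int | None = None,
              sample_id: str = "synthetic") -> tuple[EEM, SyntheticTruth]:
    """Generate an EEM as a sum of Gaussian components plus additive noise.

    Default grids cover excitation 250-500 nm and emission 300-600 nm at
    2 nm spacing, sufficient for all implemented indices.  A grid too short
    or coarse for an index triggers a warning naming the uncomputable
    indices (the EEM is still returned).
    """
    if ex_grid is None:
        ex_grid = np.arange(250.0, 500.0 + 1.0, 2.0)
    if em_grid is None:
        em_grid = np.arange(300.0, 600.0 + 1.0, 2.0)
    ex_grid = np.asarray(ex_grid, dtype=float)
    em_grid = np.asarray(em_grid, dtype=float)

    uncomputable = [
        name for name, (ex_lo, ex_hi, em_lo, em_hi) in _INDEX_REQUIREMENTS.items()
        if not (ex_grid[0] <= ex_lo and ex_hi <= ex_grid[-1]
                and em_grid[0] <= em_lo and em_hi <= em_grid[-1])
    ]
    if max(np.diff(ex_grid).max(), np.diff(em_grid).max()) > 5.0:
        uncomputable.append("(grid coarser than 5 nm)")
    if uncomputable:
        warnings.warn(f"grid cannot support indices: {uncomputable}", stacklevel=2)

    components = tuple(components)
    exx, emm = np.meshgrid(ex_grid, em_grid)
    intensities = np.zeros_like(exx)
    for comp in components:
        intensities += comp.intensity(exx, emm)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensities = intensities + rng.normal(0.0, noise_sd, size=intensities.shape)

    truth = SyntheticTruth(seed=seed, components=components)
    return EEM(sample_id, ex_grid, em_grid, intensities), truth


def synth_absorbance(a_ref: float = 20.0, S: float = 0.018,
                     grid=None, reference_wavelength: float = 254.0,
                     path_length: float = 0.01, noise_sd: float = 0.0,
                     seed: int | None = None,
                     sample_id: str = "synthetic") -> tuple[AbsorbanceSpectrum, SyntheticTruth]:
    """Exponential CDOM spectrum with Napierian a_ref (1/m) at the reference wavelength.

    The stored values are decadic cell absorbances:
    A(lambda) = a_ref * exp(S * (lambda_ref - lambda)) * path_length / ln 10,
    optionally with additive Gaussian noise of ``noise_sd`` (absorbance
    units).
    """
    if a_ref <= 0 or S <= 0:
        raise ValueError("a_ref and S must be positive")
    if grid is None:
        grid = np.arange(250.0, 500.0 + 0.5, 1.0)
    grid = np.asarray(grid, dtype=float)
    a_nap = a_ref * np.exp(S * (reference_wavelength - grid))
    decadic = a_nap * path_length / LN10
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        decadic = decadic + rng.normal(0.0, noise_sd, size=decadic.shape)
    truth = SyntheticTruth(seed=seed, cdom_slope=S, cdom_amplitude=a_ref,
                           extras={"reference_wavelength": reference_wavelength})
    return AbsorbanceSpectrum(sample_id, grid, decadic, path_length), truth


def synth_dataset(n: int = 200, b0: float = 1.0, b1: float = 0.6, b2: float = -0.3,
                  proxy_kind: str = "arix", proxy_range: tuple[float, float] = (0.2, 1.0),
                  cdoc_range: tuple[float, float] = (2.0, 30.0),
                  noise: NoiseModel = NO_NOISE, seed: int | None = None,
                  dataset_label: str = "synthetic") -> tuple[SampleTable, SyntheticTruth]:
    """Generate a DOC/A254/proxy sample table obeying the interaction model exactly.

    Per sample: draw the proxy P uniformly on ``proxy_range`` and colored DOC
    uniformly on ``cdoc_range``; set DOC = b0 + cDOC,
    A254 = cDOC / (b1 + b2 * P) and SUVA = A254 / DOC; then apply the noise
    model to DOC, proxy and A254.  Construction fails upfront if
    b1 + b2 * P can reach zero within the proxy support (the implied
    absorbance would diverge or go negative).
    """
    if proxy_kind == "suva":
        raise ValueError(
            "SUVA is derived (A254/DOC), not an independent generator input; "
            "generate with proxy_kind='arix' and fit with proxy='suva' instead"
        )
    lo, hi = proxy_range
    if b1 + b2 * lo <= 0 or b1 + b2 * hi <= 0:
        raise ValueError(
            f"b1 + b2*P must stay positive over the proxy support; "
            f"got {b1 + b2 * lo:.4g} at P={lo} and {b1 + b2 * hi:.4g} at P={hi}"
        )
    rng = np.random.default_rng(seed)
    proxy = rng.uniform(lo, hi, size=n)
    cdoc = rng.uniform(*cdoc_range, size=n)
    doc = b0 + cdoc
    a254 = cdoc / (b1 + b2 * proxy)

    doc_obs = noise.doc.perturb(doc, rng)
    tries = 0
    while np.any(doc_obs <= 0):
        tries += 1
        if tries > 100:
            raise RuntimeError("noise too large: cannot draw positive DOC")
        bad = doc_obs <= 0
        doc_obs[bad] = noise.doc.perturb(doc[bad], rng)
    proxy_obs = noise.arix.perturb(proxy, rng)
    a254_obs = noise.a254.perturb(a254, rng)

    df = pd.DataFrame({
        "sample_id": [f"{dataset_label}-{i:04d}" for i in range(n)],
        "dataset_label": dataset_label,
        "doc": doc_obs,
        "a254": a254_obs,
        "suva": a254_obs / doc_obs,
        proxy_kind if proxy_kind != "inv_s275_295" else "s275_295":
            proxy_obs if proxy_kind != "inv_s275_295"
            else 1.0 / (1000.0 * proxy_obs),  # store S in 1/nm; P was 1/S[1/um]
    })
    per_sample = pd.DataFrame({"proxy": proxy, "cdoc": cdoc, "doc": doc, "a254": a254})
    truth = SyntheticTruth(seed=seed, arint_coefficients=(b0, b1, b2),
                           proxy_kind=proxy_kind, per_sample=per_sample, noise=noise)
    return SampleTable(df, provenance="synthetic"), truth
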