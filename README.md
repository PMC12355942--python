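# domoptics

Optical proxies of dissolved organic matter (DOM) aromaticity, and DOC
prediction models that use them.

Dissolved organic carbon (DOC) concentration and aromaticity control light
attenuation, carbon fate and drinking-water treatability in inland waters.
The standard aromaticity proxy SUVA (specific UV absorbance,
A254 / DOC in m² g_C⁻¹) needs two instruments — a spectrophotometer and a
carbon analyzer — which is costly and error-prone. `domoptics` implements a
fluorescence-only alternative and the models built on it:

- **ARIX**, the aromaticity index: the ratio of emission intensities at
  520 nm and 390 nm under excitation at 320 nm, extracted from corrected
  excitation–emission matrices (EEMs). The wavelengths sit on the shoulders
  of a long-emission polyaromatic fluorophore group and a short-emission
  phenolic one, so ARIX tracks the PARAFAC score ratio **PARIX**
  (Fmax(long)/Fmax(short)) without requiring a PARAFAC decomposition.
- The classic indices FI, HIX, HIX₁₉₉₉, BIX and the freshness index β/α,
  from their standard wavelength definitions.
- CDOM absorbance utilities: Napierian absorption coefficients
  a(λ) = ln(10)·A(λ)/l, spectral slopes S₂₇₅₋₂₉₅ and S₃₈₀₋₄₄₃ by log-linear
  or nonlinear exponential fitting, and SUVA.
- A registry of published calibrations, exactly as printed:
  %(PA+PP) = 30.28·PARIX, HS/BB = 6.1·ARIX, SUVA = 6.1·ARIX − 0.7 (bulk
  waters, model II), SUVA = 4.5·ARIX (isolates, through origin), and
  percent aromaticity = 6.52·SUVA + 3.63 = 29.3·ARIX + 3.63.
- **ARINT**, the aromaticity-interaction DOC model

  DOC = b₀ + b₁·A254 + b₂·A254·P_π,

  with P_π ∈ {ARIX, SUVA, 1/S₂₇₅₋₂₉₅} entering only through the interaction
  (the proxies are undefined at zero absorbance). b₀ is uncolored DOC;
  rearranged, A254 = (DOC − b₀)/(b₁ + b₂·P_π) has Beer–Lambert form with
  molar absorptivity ∝ 1/(b₁ + b₂·P_π).
- Competitor models — the base regression DOC ~ A254, the Pan-Arctic model
  log₁₀(DOC/a₃₅₀) = C + M·S₂₇₅₋₂₉₅, and the Yan DOC_UV/DOC_LS models — with
  AIC/AICc/BIC/CAIC multimodel comparison.
- Model I (ordinary and robust bisquare) and model II (geometric-mean)
  regression, a measurement-error Monte Carlo, and a synthetic-data
  generator with closed-form ground truth for all of the above.

Everything is exercisable without external data: the generator produces
Gaussian-profile EEMs, exponential CDOM spectra and sample tables that obey
the interaction model exactly before noise.

## Worked example

```python
import numpy as np
from domoptics import arix, apply_published_model, fit_doc_model, compare_doc_models
from domoptics.synthetic import synth_eem, synth_dataset
from domoptics.sensitivity import NoiseModel, NoiseSpec

# a synthetic EEM with known fluorophore composition
eem, truth = synth_eem(seed=0)
print(arix(eem), truth.true_arix())          # 0.8866 0.8866
print(apply_published_model("suva_from_arix", arix(eem)))   # 4.708 m2/gC

# DOC prediction: generate from the interaction model, refit, compare
noise = NoiseModel(NoiseSpec("relative", 0.03), NoiseSpec("absolute", 0.0),
                   NoiseSpec("absolute", 0.0))
table, truth = synth_dataset(n=150, noise=noise, seed=42)
fit = fit_doc_model("arint", table, proxy="arix")
print(fit.b0_, fit.b1_, fit.b2_)             # 1.032, 0.603, -0.307 (true 1.0, 0.6, -0.3)
report = compare_doc_models(table, proxies=("arix",))
print(report[["rmse", "rmse_pct_change_vs_base", "preferred"]])
```

The comparison report shows the interaction model cutting prediction error
by ~81 % relative to the base regression on this data set and winning all
four information criteria:

```
             rmse  rmse_pct_change_vs_base  preferred
model
base        2.981                    0.000      False
arint_arix  0.577                  -80.654       True
```

The fitted b₁ = 0.603 is the DOC gained per unit A254 for the least
aromatic samples, and the negative b₂ = −0.307 reduces that rate as
aromaticity rises — aromatic chromophores absorb more light per carbon
atom.

A CLI mirrors the library: `domoptics synth | indices | slopes |
predict-suva | fit-doc | compare-models | simulate-noise` (each subcommand
takes `--out`, stochastic ones require `--seed`).

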