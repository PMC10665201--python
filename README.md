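# psibuffer

Quantitative analyses of how macromolecular condensation buffers water
potential. Concentrated macromolecular solutions depart from van't Hoff's
law −Ψπ = iCRT; this package fits the empirical non-ideal model

    −Ψπ = A·C / (1 − I_eff·C)

to vapour-pressure osmometry dilution series to estimate the effective
solute–water interaction I_eff (with 95% CIs, per temperature), and provides
the downstream statistics that quantify free-water release by condensation:
co-solution **additivity deviation** (how far a mixture's measured osmolality
falls below the sum of its components') and the **dilution buffering index**
(how far a cytoplasmic extract's neat osmolality falls below the linear
extrapolation of its dilution curve). On the imaging side it implements two
condensation readouts for fluorescence microscopy — the Fourier-space
**condensation ratio** (fraction of non-DC spectral power beyond a 6-px
radius) and the real-space **granulosity index** (s.d. of the high-pass
filtered signal over the ROI mean) — plus a cortical/cytosolic ratio,
threshold-based nuclear segmentation, ideal-mixing calculators for osmotic
and thermal shocks, and the small-sample statistics used for protein-set
enrichment claims (Fisher overlap test, one-proportion z-test,
Benjamini–Hochberg adjustment).

It is written for experimentalists analysing osmometry tables and microscopy
frames from condensation experiments, and every estimator ships with a
synthetic ground-truth generator (`psibuffer.synthetic`) that the test suite
uses to validate recovery, calibration and invariances end to end.

## Worked example

Fit the model to synthetic replicate curves with known truth, then score a
condensing co-solution against ideal additivity:

```python
import numpy as np
from psibuffer import fit_nonideal, additive_prediction, deviation_from_additivity
from psibuffer.synthetic import (
    SyntheticOsmoSpec, CondensingMixtureSpec,
    gen_osmometry_series, gen_condensing_mixture,
)

series = gen_osmometry_series(SyntheticOsmoSpec(seed=3))   # A=1, I_eff=0.002, 1% noise
params = fit_nonideal(series)
print(f"A = {params.A:.4f}, I_eff = {params.I_eff:.6f}, "
      f"95% CI [{params.I_eff_ci95[0]:.6f}, {params.I_eff_ci95[1]:.6f}]")

grid = np.linspace(60, 600, 19)
obs, macro, solute = gen_condensing_mixture(CondensingMixtureSpec(), grid)
pred = additive_prediction(macro, solute, (2, 1), total_conc=grid)
res = deviation_from_additivity(pred, obs)
print(f"summary deviation = {res.summary_deviation:.2f}%")
```

prints

```
A = 1.0018, I_eff = 0.001994, 95% CI [0.001987, 0.002001]
summary deviation = 11.19%
```

The fitted interaction parameter recovers the generator's 0.002 within its
confidence interval, and the co-solution's measured osmolality falls ~11%
below ideal additivity on average — the signature of water released by
condensation above the ~700 mOsm kg⁻¹ onset in the generator.

The same operations are available from a thin CLI, e.g.
`psibuffer fit --in series.csv --solute BSA --temp 27`,
`psibuffer mix-osm --part 250:325 --part 125:525`, or
`psibuffer condense --in imgs/ --cutoff 6 --pad 1024`.

## Analysis scripts

`analysis/` holds numbered narrative drivers that exercise the full pipeline
on synthetic data and write tidy tables under `results/`:

1. `01_fit_osmometry.py` — temperature-resolved I_eff fits and the
   Monte-Carlo recovery/coverage study;
2. `02_additivity_buffering.py` — co-solution additivity deviation and
   extract dilution buffering;
3. `03_image_metrics.py` — condensation ratio and granulosity index across a
   graded condensed-fraction series;
4. `04_segmentation_cortical.py` — nuclear segmentation IoU and cortical
   ratio recovery;
5. `05_enrichment_and_shocks.py` — Fisher-overlap calibration, the
   z-test against the 76.8% disordered-phosphosite background, and the
   ideal-mixing shock magnitudes.

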