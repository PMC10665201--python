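"""Fit the non-ideal osmotic model to synthetic dilution series.

Generates replicate vapour-pressure-style osmometry curves with known
(A, I_eff), fits them pooled, and summarizes how well the solute–water
interaction parameter is recovered — including a temperature ramp in which
the generator's I_eff falls linearly with temperature, mimicking how
macromolecule hydration grows as solutions cool.

Writes results/ieff_temperature.csv and results/fit_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from psibuffer.osmo_model import fit_nonideal, ieff_temperature_profile
from psibuffer.synthetic import SyntheticOsmoSpec, gen_osmometry_series

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

# --- temperature ramp: I_eff(T) decreasing with T, 1% reading noise ---------
temps_c = [17.0, 22.0, 27.0, 32.0, 37.0]
by_t = {
    t: gen_osmometry_series(
        SyntheticOsmoSpec(ieff_slope=2e-5, seed=100 + i), temperature=t
    )
    for i, t in enumerate(temps_c)
}
rows = []
for t_k, params in ieff_temperature_profile(by_t):
    spec = SyntheticOsmoSpec(ieff_slope=2e-5)
    rows.append(
        {
            "temperature_C": round(t_k - 273.15, 2),
            "I_eff": params.I_eff,
            "I_eff_lo": params.I_eff_ci95[0],
            "I_eff_hi": params.I_eff_ci95[1],
            "I_eff_true": spec.ieff_at(t_k),
            "A": params.A,
            "n_curves": params.n_curves,
        }
    )
profile = pd.DataFrame(rows)
profile.to_csv(OUT / "ieff_temperature.csv", index=False)

# --- Monte-Carlo recovery under the study's noise conditions ----------------
recs = []
for k in range(200):
    spec = SyntheticOsmoSpec(seed=5000 + k)
    p = fit_nonideal(gen_osmometry_series(spec))
    recs.append(
        {
            "sim": k,
            "A_rel_err": abs(p.A - spec.A_true) / spec.A_true,
            "Ieff_rel_err": abs(p.I_eff - spec.I_eff_true) / spec.I_eff_true,
            "ci_covers": p.I_eff_ci95[0] <= spec.I_eff_true <= p.I_eff_ci95[1],
        }
    )
rec = pd.DataFrame(recs)
rec.to_csv(OUT / "fit_recovery.csv", index=False)

print("I_eff versus temperature (fitted vs generator truth):")
print(profile[["temperature_C", "I_eff", "I_eff_true"]].to_string(index=False))
trend = "falls" if profile["I_eff"].is_monotonic_decreasing else "does not fall"
print(f"\nFitted I_eff {trend} monotonically as temperature rises, "
      "matching the generator's hydration-growth trend.")
print(
    f"\nRecovery over {len(rec)} noisy simulations: median |dA|/A = "
    f"{100 * rec['A_rel_err'].median():.2f}%, median |dI|/I = "
    f"{100 * rec['Ieff_rel_err'].median():.2f}%, CI coverage = "
    f"{100 * rec['ci_covers'].mean():.1f}%."
)
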