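"""Quantify free-water release: co-solution additivity and dilution buffering.

A co-solution of an ideal solute and a condensing macromolecule is compared
with the sum of its components' osmolalities; once the additive osmolality
crosses the condensation threshold, the observed readings fall short of
additivity — the shortfall (percent deviation) measures water released from
hydration layers.  The same water-release model, run along a dilution series,
yields a sub-linear curve near the neat sample whose departure from the
linear extrapolation is the buffering index.

Writes results/additivity.csv and results/buffering.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from psibuffer.osmo_model import (
    additive_prediction,
    deviation_from_additivity,
    dilution_buffering_index,
)
from psibuffer.synthetic import (
    CondensingMixtureSpec,
    gen_buffered_dilution,
    gen_condensing_mixture,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

grid = np.linspace(60.0, 600.0, 19)
rows = []
for label, spec in [
    ("condensing", CondensingMixtureSpec()),
    ("ideal", CondensingMixtureSpec(hydration_release_frac=0.0)),
]:
    obs, macro, solute = gen_condensing_mixture(spec, grid)
    pred = additive_prediction(macro, solute, (2.0, 1.0), total_conc=grid)
    res = deviation_from_additivity(pred, obs)
    for c, p, o, dv in zip(grid, res.predicted, res.observed, res.percent_deviation):
        rows.append(
            {"mixture": label, "total_conc": c, "predicted": p, "observed": o,
             "percent_deviation": dv}
        )
    print(
        f"{label} 2:1 co-solution: summary deviation "
        f"{res.summary_deviation:.2f}% "
        f"(max per-point {np.nanmax(res.percent_deviation):.2f}%)"
    )
pd.DataFrame(rows).to_csv(OUT / "additivity.csv", index=False)

d = np.linspace(0.05, 1.0, 12)
buff_rows = []
for label, spec in [
    ("buffered", CondensingMixtureSpec(I_eff=0.0025, hydration_release_frac=1.0,
                                       steepness=0.02)),
    ("ideal", CondensingMixtureSpec(I_eff=0.0, hydration_release_frac=0.0)),
]:
    _, osm = gen_buffered_dilution(spec, d)
    res = dilution_buffering_index(d, osm, d_lin=0.3)
    for f, o, lp in zip(d, osm, res.linear_prediction):
        buff_rows.append(
            {"extract": label, "fraction": f, "osmolality": o, "linear_prediction": lp}
        )
    print(f"{label} extract: buffering index {res.buffering_index:.4f}")
pd.DataFrame(buff_rows).to_csv(OUT / "buffering.csv", index=False)

print(
    "\nThe condensing mixture departs from additivity only above the "
    "condensation threshold, and the buffered extract's neat osmolality sits "
    "below the linear extrapolation — both signatures of water release by "
    "condensation."
)
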