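#!/usr/bin/env python
"""Mixed-model and linear-model inference.

Fits the repeated-measures mixed model to the sigma table (treatment and
SPL fixed, animal identity and SPL as crossed random intercepts,
Satterthwaite t tests) and ordinary linear models to a simulated
morphometry table (nerve width and neuron count against age and
treatment).  Writes results/lmem.json and results/morphometry_lm.json.
"""

from pathlib import Path

import pandas as pd

from nervedose import (ModelSpec, MorphometrySimConfig, cohens_d, fit_lm,
                       fit_lmem, simulate_morphometry)
from nervedose.io import write_json, write_table

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main():
    table = pd.read_csv(RESULTS / "sigma.csv")
    spec = ModelSpec(response="sigma",
                     fixed=("treatment", "spl_db", "treatment:spl_db"),
                     random=("animal_id", "spl_db"))
    fit = fit_lmem(spec, table)
    write_json(fit.to_dict(), RESULTS / "lmem.json")
    print("sigma ~ treatment * SPL + (1|animal) + (1|SPL):")
    print(fit.summary_frame().round(4).to_string(index=False))
    top = table.spl_db.max()
    sub = table[table.spl_db == top]
    d = cohens_d(sub[sub.treatment == "noise"].sigma,
                 sub[sub.treatment == "control"].sigma)
    print(f"Cohen's d (noise - control) at {top:.0f} dB SPL: {d:.2f}")

    morph = simulate_morphometry(MorphometrySimConfig(seed=20220722))
    write_table(morph, RESULTS / "morphometry.csv")
    out = {}
    for measure in ("neuron_count", "nerve_width_um"):
        lm = fit_lm(ModelSpec(response=measure, fixed=("day", "treatment")),
                    morph)
        out[measure] = lm.to_dict()
        i_day, i_tr = lm.coef_index("day"), lm.coef_index("treatment")
        print(f"{measure}: age t({lm.df[i_day]:.0f}) = {lm.t[i_day]:+.2f} "
              f"(p = {lm.pvalues[i_day]:.3g}); "
              f"noise t = {lm.t[i_tr]:+.2f} (p = {lm.pvalues[i_tr]:.3g})")
    write_json(out, RESULTS / "morphometry_lm.json")


if __name__ == "__main__":
    main()
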