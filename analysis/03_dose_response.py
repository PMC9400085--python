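#!/usr/bin/env python
"""Dose-response modelling of the sigma table.

Fits a four-parameter log-linear curve per treatment group and a pooled
treatment-omitted curve, reports the per-parameter t tests and the
extra-sum-of-squares F statistic, and saves a diagnostic figure of the
fits.  Writes results/dose_fit.json and results/dose_response.png.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nervedose import fit_grouped_fourpl, fourpl, treatment_F
from nervedose.io import write_json

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main():
    table = pd.read_csv(RESULTS / "sigma.csv")
    grouped = fit_grouped_fourpl(table)
    comp = treatment_F(grouped)
    write_json({"fits": grouped.to_dict(), "comparison": comp.to_dict()},
               RESULTS / "dose_fit.json")

    for g, fit in grouped.group_fits.items():
        p = fit.params
        print(f"{g:>8}: b={p.b:+.3f}  c={p.c:.2f}  d={p.d:.2f}  e={p.e:.1f} dB"
              f"  (rss {fit.rss:.3f})")
    print(f"treatment F({comp.F_df[0]},{comp.F_df[1]}) = {comp.F:.1f}, "
          f"p = {comp.F_p:.3g}")
    for name in ("b", "d", "e"):
        print(f"  {name}: diff = {comp.param_diff[name]:+.3f}, "
              f"t = {comp.param_t[name]:+.2f}, p = {comp.param_p[name]:.3g}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping figure")
        return
    fig, ax = plt.subplots(figsize=(5, 3.5))
    xs = np.linspace(20, 110, 200)
    colors = {"control": "0.4", "noise": "crimson"}
    for g, fit in grouped.group_fits.items():
        sub = table[table.treatment == g]
        ax.plot(sub.spl_db, sub.sigma, ".", color=colors[g], alpha=0.4)
        ax.plot(xs, fourpl(xs, fit.params), color=colors[g], lw=2, label=g)
    ax.set_xlabel("SPL (dB)")
    ax.set_ylabel(r"$\sigma$ ratio")
    ax.legend(frameon=False)
    ax.set_title(f"F = {comp.F:.0f}")
    fig.tight_layout()
    fig.savefig(RESULTS / "dose_response.png", dpi=120)
    print(f"figure -> {RESULTS / 'dose_response.png'}")


if __name__ == "__main__":
    main()
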