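#!/usr/bin/env python
"""Power analysis: a-priori sample size and simulated mixed-model power.

Reproduces the planning calculations: the analytic noncentral-t a-priori
sample size for the morphometry comparison (d = 1.45, 95% power,
one-sided alpha 0.05) and a Monte-Carlo power curve for the mixed-model
treatment test as the cohort grows.  Writes results/power.json.
"""

import dataclasses
from pathlib import Path

from nervedose import (CONTROL_TRUTH, DoseResponseSimConfig, FourPLParams,
                       ModelSpec, a_priori_n, simulate_power_lmem,
                       t_test_power)
from nervedose.io import write_json

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main():
    d = 1.45
    n_total = a_priori_n(d, 0.95, 0.05, "one")
    p_at_n = t_test_power(d, n_total // 2, 0.05, "one")
    print(f"a-priori t test: d = {d}, one-sided alpha 0.05, target 95% "
          f"-> total N = {n_total} (power {100 * p_at_n:.1f}%)")

    truth = DoseResponseSimConfig(
        truth_per_group={"control": CONTROL_TRUTH,
                         "noise": FourPLParams(-0.15, 1.0, 7.0, 75.0)},
        n_animals_per_group=6, animal_intercept_sd=0.5, residual_sd=0.3,
        spl_levels=(30.0, 50.0, 70.0, 90.0, 110.0), seed=0)
    spec = ModelSpec(response="sigma", fixed=("treatment", "spl_db"),
                     random=("animal_id",))
    curve = {}
    for n in (6, 9, 12):
        cfg = dataclasses.replace(truth, n_animals_per_group=n)
        res = simulate_power_lmem(cfg, spec, n_sims=300, alpha=0.05, seed=5)
        curve[n] = res.to_dict()
        print(f"LMEM power at {n} animals/group: {res.power:.2f} "
              f"(95% CI {res.ci[0]:.2f}-{res.ci[1]:.2f}, {res.n_sims} sims)")

    write_json({"a_priori": {"d": d, "total_n": n_total, "power": p_at_n},
                "lmem_power_curve": curve}, RESULTS / "power.json")
    print(f"-> {RESULTS / 'power.json'}")


if __name__ == "__main__":
    main()
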