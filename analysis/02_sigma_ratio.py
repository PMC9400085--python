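#!/usr/bin/env python
"""Quantify tone-evoked nerve activity: sigma ratios for every recording.

Reads the WAV + JSON pairs written by 01_simulate_recordings.py,
rectifies each trace, integrates tone and background windows and writes
the long-format sigma table to results/sigma.csv.
"""

import json
from pathlib import Path

import pandas as pd

from nervedose import ToneProtocol, sigma_ratio
from nervedose.io import read_trace, validate_table, write_table

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main():
    manifest = json.loads((RESULTS / "cohort_manifest.json").read_text())
    proto = ToneProtocol(**manifest["protocol"])
    parts = []
    for rec in manifest["animals"]:
        trace = read_trace(rec["wav"], rec["meta"])
        parts.append(sigma_ratio(trace, proto))
    table = pd.concat(parts, ignore_index=True)
    validate_table(table, "sigma")
    out = write_table(table, RESULTS / "sigma.csv")
    peak = table.groupby("treatment")["sigma"].max()
    print(f"sigma table: {len(table)} rows -> {out}")
    print("maximal sigma per group:")
    print(peak.to_string())


if __name__ == "__main__":
    main()
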