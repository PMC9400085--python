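#!/usr/bin/env python
"""Simulate a cohort of hook-electrode recordings.

Generates nerve traces for a control and a noise-exposed group under the
default tone protocol (3 kHz tones, 20-110 dB SPL, 3 repetitions, 60 s
baseline, 25 kHz sampling), using a reduced cohort of 4 animals per
group so the script stays interactive.  Waveforms (binary WAV) go to
scratch/, the cohort manifest to results/.
"""

import json
from pathlib import Path

import numpy as np

from nervedose import (CONTROL_TRUTH, NOISE_TRUTH, NerveSimConfig,
                       ToneProtocol, simulate_nerve_trace)
from nervedose.io import write_trace

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "traces"
RESULTS = ROOT / "results"

N_PER_GROUP = 4
SEED = 20220721


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    proto = ToneProtocol()
    seeds = np.random.SeedSequence(SEED).spawn(2 * N_PER_GROUP)
    manifest = {"protocol": proto.to_dict(), "animals": []}
    i = 0
    for group, truth in (("control", CONTROL_TRUTH), ("noise", NOISE_TRUTH)):
        for k in range(N_PER_GROUP):
            s = int(seeds[i].generate_state(1)[0] % (2 ** 31))
            i += 1
            animal = f"{group}_{k:02d}"
            cfg = NerveSimConfig(evoked_curve=truth, seed=s)
            trace = simulate_nerve_trace(
                proto, cfg, meta={"animal_id": animal, "treatment": group,
                                  "day": 1})
            wav, meta = write_trace(trace, SCRATCH / f"{animal}.wav")
            manifest["animals"].append({"animal_id": animal, "group": group,
                                        "seed": s, "wav": str(wav),
                                        "meta": str(meta)})
            print(f"{animal}: {trace.n_samples} samples "
                  f"({trace.duration:.0f} s at {proto.sampling_rate:.0f} Hz)")
    out = RESULTS / "cohort_manifest.json"
    out.write_text(json.dumps(manifest, indent=2))
    print(f"\nSimulated {i} recordings; manifest at {out}")


if __name__ == "__main__":
    main()
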