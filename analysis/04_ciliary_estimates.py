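#!/usr/bin/env python
"""Ciliary propulsion estimates for the representative ciliate cohort.

Inverts the three ciliary models for each fixture ciliate's observed
swimming speed: effective tangential surface stress τ (model A), effective
force per cilium F (model B, where ciliation data exist) and effective
surface slip speed û_s (squirmer model C).  Reports the cohort min/max
envelopes — the per-species spread is large, which is exactly why no single
universal stress/force/slip value describes all ciliates.

Writes results/ciliary_estimates.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from microswim.datasets import ciliate_records
from microswim.fluid import WATER_25C
from microswim.pipeline import results_frame, run_estimation

OUT = Path(__file__).resolve().parents[1] / "results"

UNITS = {"stress": "mPa", "force": "pN", "surface": "um/s"}


def main() -> None:
    records = ciliate_records()
    frames = []
    print(f"Ciliary model inversions over {len(records)} fixture ciliates:\n")
    for model, units in UNITS.items():
        results, bounds = run_estimation(records, model, WATER_25C)
        frame = results_frame(results)
        frame["model"] = model
        frames.append(frame)
        print(f"  model {model:8s}: {bounds.min:9.3g} to {bounds.max:9.3g} {units} "
              f"(min {bounds.argmin}, max {bounds.argmax}; "
              f"{bounds.n_used} used, {bounds.n_skipped} skipped)")
    OUT.mkdir(exist_ok=True)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(OUT / "ciliary_estimates.csv", index=False)
    print("\nThe order-of-magnitude spread within each model rules out a "
          "universal per-organism constant; the envelopes are the usable output.")
    print(f"wrote {OUT / 'ciliary_estimates.csv'}")


if __name__ == "__main__":
    main()
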