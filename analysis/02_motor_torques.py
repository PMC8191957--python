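#!/usr/bin/env python
"""Bacterial motor torques from resistive-force theory.

Applies the simplified speed–torque relation T_m = U·η·ξ², with the
morphological factor ξ² = 9πh·(B·C_FB + L/(ln(L/b)+1/2)), to the two
species whose tabulated geometry sets the extremes of the prokaryote
cohort.  The resulting bounds — about 27.5 pN·nm for the slow archaeon
Halobacterium salinarum and about 1907 pN·nm for the fast swimmer
Pseudomonas fluorescens — bracket most direct motor-torque measurements
(tens to a few thousand pN·nm).

Writes results/motor_torques.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from microswim.datasets import torque_bound_records
from microswim.fluid import WATER_25C
from microswim.pipeline import results_frame, run_estimation

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    results, bounds = run_estimation(torque_bound_records(), "rft_torque", WATER_25C)
    OUT.mkdir(exist_ok=True)
    frame = results_frame(results)
    frame.to_csv(OUT / "motor_torques.csv", index=False)

    print("Effective flagellar motor torques (2b = 0.02 um, water at 25 C):\n")
    for r in results:
        xi = r.inputs["xi_sq"]
        print(f"  {r.species:25s} xi^2 = {xi:7.3f} um^2   T_m = {r.value:8.2f} pN nm")
    print(f"\nCohort torque range: {bounds.min:.2f} ({bounds.argmin}) to "
          f"{bounds.max:.0f} pN nm ({bounds.argmax}).")
    print(f"wrote {OUT / 'motor_torques.csv'}")


if __name__ == "__main__":
    main()
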