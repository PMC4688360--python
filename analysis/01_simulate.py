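#!/usr/bin/env python
"""Simulate one control and one chronically-stressed animal.

Renders the default acquisition protocol (8 trials, 200 frames at 10 Hz,
5-s hindpaw-stimulus analogue at t = 5 s) for the two study conditions and
writes the trial stacks plus ground truth under scratch/sim/<group>/, and
the injected parameters to results/simulated_animals.csv.

These animals are rendered without artery dilation so the downstream CBV
analysis (02) reads the parenchymal amplitude cleanly; artery dynamics are
analysed in 04 from its own renders.
"""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

from oisdyn import synthetic as syn

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    rows = []
    for group, base in (("control", syn.CONTROL_PARAMS), ("stress", syn.STRESS_PARAMS)):
        params = dataclasses.replace(base, rng_seed=seed, dilation_pct=0.0)
        truth = syn.generate_vessel_tree(params)
        trials = syn.render_trials(params, truth)
        outdir = ROOT / "scratch" / "sim" / group
        syn.save_scenario(params, truth, trials, outdir)
        rows.append(
            {
                "group": group,
                "peak_amplitude_pct": params.peak_amplitude_pct,
                "time_to_peak_s": params.time_to_peak_s,
                "dilation_pct": params.dilation_pct,
                "vessel_fraction": truth.vessel_mask.mean(),
                "n_trials": params.n_trials,
                "stacks_dir": str(outdir),
            }
        )
        print(f"{group}: {params.n_trials} trials -> {outdir} "
              f"(vessel fraction {truth.vessel_mask.mean():.2f})")
    out = ROOT / "results" / "simulated_animals.csv"
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
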