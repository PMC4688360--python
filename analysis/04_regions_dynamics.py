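#!/usr/bin/env python
"""Region decomposition and pial-artery dynamics for small cohorts.

Runs the full vascular chain (pixel classification, SD map, responsive
area, four-region decomposition, pixel-count dilation trace) for 6 control
and 5 stressed synthetic animals and writes per-animal metrics. Healthy
animals dilate their responsive pial arteries by ~6.5% of pixel count,
stressed ones by ~3.5%; vessels outside the responsive area barely change.
"""

import sys
from pathlib import Path

from oisdyn import benchmarks

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    df = benchmarks.vascular_group_benchmark(seed=seed)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    df.to_csv(results / "vascular_metrics.csv", index=False)
    print(df.to_string(index=False))
    g = df.groupby("group")[["max_dilation_pct", "nonresponsive_dilation_pct", "vessel_iou"]].mean()
    print("\ngroup means:\n", g.to_string())
    print(f"wrote {results / 'vascular_metrics.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
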