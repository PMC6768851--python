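#!/usr/bin/env python
"""Quantify simulated wound-healing wells across closure rates.

Simulates wells whose scratch closes at 5, 10 and 20 px/h (image width
600 px, 30 min cadence), runs the full structure-map -> threshold ->
series -> rate pipeline on each, and tabulates recovered vs true rates.
Writes results/wound_healing_rates.csv and prints the recovery summary.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from motilitykit.pipeline import quantify_simulated_well
from motilitykit.synthetic import ScratchSimParams

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 0
N_SEEDS = 5


def main() -> None:
    rows = []
    rng = np.random.default_rng(SEED)
    for v in (5.0, 10.0, 20.0):
        for _ in range(N_SEEDS):
            params = ScratchSimParams(
                closure_rate=v, n_frames=27, seed=int(rng.integers(0, 2**31 - 1))
            )
            fit = quantify_simulated_well(params)
            rows.append({
                "true_rate_px_h": v,
                "true_rate_frac_h": v / params.image_width,
                "estimated_rate_frac_h": fit.rate,
                "n_points": fit.n_points,
            })
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "wound_healing_rates.csv", index=False,
                 float_format="%.6f")

    summary = table.groupby("true_rate_px_h").apply(
        lambda g: 100 * abs(g.estimated_rate_frac_h.mean()
                            - g.true_rate_frac_h.iloc[0])
        / g.true_rate_frac_h.iloc[0],
        include_groups=False,
    )
    print("Recovered closure rates (mean relative error % per condition):")
    print(summary.round(2).to_string())
    print("\nEstimated rates rise with true rates:",
          table.groupby("true_rate_px_h").estimated_rate_frac_h.mean()
          .is_monotonic_increasing)
    print(f"wrote {OUT / 'wound_healing_rates.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
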