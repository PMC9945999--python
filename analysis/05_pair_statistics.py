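#!/usr/bin/env python
"""Statistical-pair populations across the quenching concentration range.

Tabulates, for concentrations spanning the onset (0.014 mol dm^-3, ~50%
quenching) to saturation (0.1 mol dm^-3, ~100% quenching), the fraction of
chlorophyll molecules with a neighbor within 1 nm — by the expected-count,
Poisson and free-volume conventions — and verifies the Poisson value by
seeded Monte Carlo.  A few percent of paired molecules at the onset
concentration is enough once excitation migration funnels energy to them.
"""

import argparse
from pathlib import Path

import pandas as pd

from chlquench.pairs import PairConfig, paired_fraction, paired_fraction_mc

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/pair_statistics.csv"))
args = parser.parse_args()

rows = []
for conc in (0.005, 0.014, 0.05, 0.1):
    row = {"concentration_molar": conc, "cutoff_nm": 1.0}
    for method in ("expected_count", "poisson", "expected_count_free_volume"):
        cfg = PairConfig(concentration=conc, cutoff=1.0, method=method)
        row[method] = paired_fraction(cfg)
    mc, se = paired_fraction_mc(
        PairConfig(concentration=conc, cutoff=1.0, method="poisson"),
        n_molecules=2000, n_replicates=20, seed=args.seed,
    )
    row["mc_poisson"] = mc
    row["mc_stderr"] = se
    rows.append(row)

table = pd.DataFrame(rows)
args.out.parent.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out, index=False)

print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\nat 0.014 mol/dm3 ~{100 * table.loc[1, 'expected_count']:.0f}% of "
      "molecules sit within 1 nm of a partner; at 0.1 mol/dm3 "
      f"~{100 * table.loc[3, 'expected_count']:.0f}%")
print(f"wrote {args.out}")
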