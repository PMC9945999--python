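#!/usr/bin/env python
"""Reconstruct the free-energy surfaces and extract Marcus parameters.

Reads the synthetic trajectories from step 01, fits the gap distributions,
builds the quadratic surfaces and reports lambda and dA with their 95%
envelopes, by both routes: the companion construction on the CS trajectory
(V_ES = V_CS + dE) and the crossfit construction anchored to the GS
trajectory via the linear gap relation.  The two routes agreeing is the
self-consistency check that justifies extrapolating the quadratic form.
"""

import argparse
import json
from pathlib import Path

from chlquench.constants import thermal_energy
from chlquench.fes import (
    Axis,
    build_sampled_fes,
    companion_surface,
    crossfit_es_surface,
    fit_gap_distribution,
    fit_gap_relation,
    propagate_uncertainty,
    summarize_surface_pair,
)
from chlquench.io import validate_energy_table

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results/surfaces.json"))
parser.add_argument("--temperature", type=float, default=300.0)
args = parser.parse_args()
kt = thermal_energy(args.temperature)

cs_table = validate_energy_table(args.data / "cs_trajectory.csv")
gaps = (cs_table["E_ES_eV"] - cs_table["E_CS_eV"]).to_numpy()
fit = fit_gap_distribution(gaps)
cs_fes = build_sampled_fes(fit, args.temperature,
                           sampled_range=(gaps.min(), gaps.max()))
companion = summarize_surface_pair(companion_surface(cs_fes), cs_fes)
lam_lo, lam_hi, _ = propagate_uncertainty(
    {"sigma": (fit.sigma, fit.sigma_ci)}, lambda sigma: sigma**2 / (2 * kt)
)
da_lo, da_hi, _ = propagate_uncertainty(
    {"mu": (fit.mu, fit.mu_ci), "sigma": (fit.sigma, fit.sigma_ci)},
    lambda mu, sigma: sigma**2 / (2 * kt) - mu,
)

gs_table = validate_energy_table(args.data / "gs_trajectory.csv")
x = (gs_table["E_CS_eV"] - gs_table["E_GS_eV"]).to_numpy()
y = (gs_table["E_ES_eV"] - gs_table["E_CS_eV"]).to_numpy()
relation = fit_gap_relation(x, y)
fit_x = fit_gap_distribution(x, axis=Axis.CS_MINUS_GS, trajectory="GS")
cs_on_gs = build_sampled_fes(fit_x, args.temperature)
crossfit = summarize_surface_pair(
    crossfit_es_surface(cs_on_gs, relation).surface, cs_on_gs
)

report = {
    "companion_route": {
        "lambda_eV": companion.lambda_reorg,
        "lambda_bounds_eV": [lam_lo, lam_hi],
        "delta_A_eV": companion.delta_a,
        "delta_A_bounds_eV": [da_lo, da_hi],
        "crossing_above_es_min_eV": companion.crossing_energy_above_es_min,
        "marcus_region": companion.marcus_region,
    },
    "crossfit_route": {
        "lambda_eV": crossfit.lambda_reorg,
        "delta_A_eV": crossfit.delta_a,
        "relation_slope": relation.slope_a,
        "relation_intercept_eV": relation.intercept_b,
        "relation_r": relation.r_value,
    },
}
args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(report, indent=2) + "\n")

print(f"companion route: lambda = {companion.lambda_reorg:.3f} "
      f"[{lam_lo:.3f}, {lam_hi:.3f}] eV, dA = {companion.delta_a:.3f} "
      f"[{da_lo:.3f}, {da_hi:.3f}] eV")
print(f"crossfit route:  lambda = {crossfit.lambda_reorg:.3f} eV, "
      f"dA = {crossfit.delta_a:.3f} eV "
      f"(gap relation: slope {relation.slope_a:.3f}, r = {relation.r_value:.3f})")
print(f"route disagreement: "
      f"|d lambda| = {abs(companion.lambda_reorg - crossfit.lambda_reorg):.3f} eV")
print(f"wrote {args.out}")
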