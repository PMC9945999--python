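"""Synthetic trajectory-level data with the statistical structure the analysis assumes.

An external MD + semiempirical engine produces, for each trajectory frame, the
energies of the ground (GS), charge-separated (CS) and photoexcited (ES)
states of a chlorophyll pair.  Downstream analysis uses only three facts about
those tables:

* on the CS trajectory the vertical gap ``dE = E_ES - E_CS`` is Gaussian,
* on the GS trajectory the gap ``x = E_CS - E_GS`` is Gaussian and the gap
  ``y = E_ES - E_CS`` is (noisily) linear in ``x``,
* donor/acceptor electronic couplings are positive with an
  orders-of-magnitude spread.

This module generates tables with exactly that structure, plus random
hard-sphere molecular placements used as the Monte-Carlo oracle for the
solution pair statistics.  Absolute energies are arbitrary up to a per-frame
constant (only gaps enter the analysis), so each generator pins a reference
state to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import thermal_energy

__all__ = [
    "GapModelSpec",
    "CouplingModelSpec",
    "default_cs_spec",
    "generate_cs_trajectory",
    "generate_gs_trajectory",
    "generate_couplings",
    "generate_random_placement",
]

ENERGY_COLUMNS = ["frame", "E_GS_eV", "E_CS_eV", "E_ES_eV"]
COUPLING_COLUMNS = ["frame", "H_hh_eV", "H_ll_eV"]


@dataclass(frozen=True)
class GapModelSpec:
    """Statistical model of the vertical energy gaps along the two trajectories.

    Parameters
    ----------
    mu_cs, sigma_cs:
        Mean and SD (eV) of ``dE = E_ES - E_CS`` sampled on the CS trajectory.
    mu_gs_axis, sigma_gs_axis:
        Mean and SD (eV) of ``x = E_CS - E_GS`` sampled on the GS trajectory.
    slope_a, intercept_b:
        Linear relation ``y = a*x + b`` between ``y = E_ES - E_CS`` and ``x``
        on the GS trajectory (slope dimensionless, intercept eV).
    resid_sd:
        SD (eV) of the Gaussian residual around that line; 0 is allowed and
        gives an exactly linear relation.
    n_frames:
        Number of frames per generated table (>= 2).
    seed:
        RNG seed; a fixed seed gives byte-identical tables.
    """

    mu_cs: float = 0.27
    sigma_cs: float = 0.1847
    mu_gs_axis: float = 3.26
    sigma_gs_axis: float = 0.3695
    slope_a: float = -0.5
    intercept_b: float = 1.9
    resid_sd: float = 0.02
    n_frames: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma_cs > 0:
            raise ValueError(f"sigma_cs must be > 0, got {self.sigma_cs}")
        if not self.sigma_gs_axis > 0:
            raise ValueError(
                f"sigma_gs_axis must be > 0, got {self.sigma_gs_axis}"
            )
        if self.resid_sd < 0:
            raise ValueError(f"resid_sd must be >= 0, got {self.resid_sd}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        for name in ("mu_cs", "mu_gs_axis", "slope_a", "intercept_b"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class CouplingModelSpec:
    """Log-normal model of donor/acceptor coupling magnitudes.

    ``log10 |H|`` is Normal(log10_center, log10_spread), giving the broad,
    positively skewed, strictly positive coupling distribution seen when the
    coupling is evaluated over a thermal ensemble of pair orientations.  The
    defaults emulate a 500-frame thermal ensemble of a 10 A chlorophyll
    pair whose couplings span roughly 1e-4 to 0.1 eV: a 3-decade sample
    range (+-3 SD over 500 draws) with the expected maximum (~3 SD above
    the centre) at ~0.11 eV.
    """

    log10_center: float = -2.5
    log10_spread: float = 0.5
    n_samples: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.log10_spread < 0:
            raise ValueError(
                f"log10_spread must be >= 0, got {self.log10_spread}"
            )
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")


def default_cs_spec(
    lambda_reorg: float = 0.66,
    delta_a: float = 0.39,
    temperature: float = 300.0,
    n_frames: int = 500,
    seed: int = 0,
) -> GapModelSpec:
    """Gap-model spec whose CS-trajectory statistics reproduce given Marcus parameters.

    Inverts the linear-response closed forms lambda = sigma^2/(2kT) and
    dA = sigma^2/(2kT) - mu, i.e. sigma = sqrt(2*kT*lambda) and
    mu = lambda - dA.  The default (0.66 eV, 0.39 eV) emulates a
    solvated chlorophyll pair at the 10 A critical separation.
    """
    kt = thermal_energy(temperature)
    sigma = float(np.sqrt(2.0 * kt * lambda_reorg))
    mu = lambda_reorg - delta_a
    return GapModelSpec(
        mu_cs=mu, sigma_cs=sigma, n_frames=n_frames, seed=seed
    )


def generate_cs_trajectory(spec: GapModelSpec) -> pd.DataFrame:
    """Per-frame state-energy table for the charge-separated-state trajectory.

    The CS energy is used as the per-frame reference (E_CS = 0), so the
    sampled gap dE = E_ES - E_CS is carried exactly by E_ES.  E_GS is offset
    by the GS-axis mean so all three columns are populated; only gaps are
    meaningful downstream.
    """
    rng = np.random.default_rng(spec.seed)
    gap = rng.normal(spec.mu_cs, spec.sigma_cs, spec.n_frames)
    return pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "E_GS_eV": np.full(spec.n_frames, -spec.mu_gs_axis),
            "E_CS_eV": np.zeros(spec.n_frames),
            "E_ES_eV": gap,
        }
    )


def generate_gs_trajectory(spec: GapModelSpec) -> pd.DataFrame:
    """Per-frame state-energy table for the neutral ground-state trajectory.

    Samples x = E_CS - E_GS ~ Normal(mu_gs_axis, sigma_gs_axis) and
    y = E_ES - E_CS = a*x + b + Normal(0, resid_sd), then reconstructs
    absolute energies with E_GS = 0 as reference.
    """
    # derive a distinct stream from the same seed so the CS and GS tables
    # generated from one spec are independent
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    x = rng.normal(spec.mu_gs_axis, spec.sigma_gs_axis, spec.n_frames)
    y = spec.slope_a * x + spec.intercept_b
    if spec.resid_sd > 0:
        y = y + rng.normal(0.0, spec.resid_sd, spec.n_frames)
    return pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "E_GS_eV": np.zeros(spec.n_frames),
            "E_CS_eV": x,
            "E_ES_eV": x + y,
        }
    )


def generate_couplings(spec: CouplingModelSpec) -> pd.DataFrame:
    """Per-frame HOMO-HOMO and LUMO-LUMO coupling magnitudes (eV), log-normal."""
    rng = np.random.default_rng(spec.seed)
    h_hh = 10.0 ** rng.normal(spec.log10_center, spec.log10_spread, spec.n_samples)
    h_ll = 10.0 ** rng.normal(spec.log10_center, spec.log10_spread, spec.n_samples)
    return pd.DataFrame(
        {"frame": np.arange(spec.n_samples), "H_hh_eV": h_hh, "H_ll_eV": h_ll}
    )


def generate_random_placement(
    n_molecules: int,
    box_side: float,
    r_excl: float = 0.0,
    seed: int = 0,
    max_attempts_per_molecule: int = 10_000,
) -> np.ndarray:
    """Uniform random points in a periodic cubic box with a hard-sphere exclusion.

    Points are inserted sequentially; a candidate closer than ``r_excl`` to an
    accepted point (minimum-image convention) is rejected and redrawn.  The
    periodic convention makes the finite box emulate the infinite uniform
    medium assumed by the analytic pair estimator, removing edge depletion.

    Parameters
    ----------
    n_molecules : number of points; 0 returns an empty (0, 3) array.
    box_side : cubic box edge, nm.
    r_excl : minimum allowed pair separation, nm.
    seed : RNG seed.
    max_attempts_per_molecule : rejection budget per point before giving up.

    Returns
    -------
    (n_molecules, 3) array of coordinates in [0, box_side).

    Raises
    ------
    ValueError
        If the packing is infeasible (rejection budget exhausted) or the
        exclusion diameter exceeds what the periodic box can host.
    """
    if n_molecules < 0:
        raise ValueError(f"n_molecules must be >= 0, got {n_molecules}")
    if box_side <= 0:
        raise ValueError(f"box_side must be > 0, got {box_side}")
    if r_excl < 0:
        raise ValueError(f"r_excl must be >= 0, got {r_excl}")
    if n_molecules > 1 and r_excl >= box_side / 2.0:
        raise ValueError(
            "r_excl must be smaller than half the box side under the "
            f"minimum-image convention, got r_excl={r_excl}, box={box_side}"
        )
    points = np.empty((n_molecules, 3))
    if n_molecules == 0:
        return points
    rng = np.random.default_rng(seed)
    half = box_side / 2.0
    n_placed = 0
    while n_placed < n_molecules:
        for _ in range(max_attempts_per_molecule):
            candidate = rng.uniform(0.0, box_side, 3)
            if n_placed == 0 or r_excl == 0.0:
                break
            delta = np.abs(points[:n_placed] - candidate)
            delta = np.where(delta > half, box_side - delta, delta)
            if np.min(np.einsum("ij,ij->i", delta, delta)) >= r_excl**2:
                break
        else:
            raise ValueError(
                f"could not place molecule {n_placed + 1}/{n_molecules}: "
                f"packing fraction too high for r_excl={r_excl} nm in a "
                f"{box_side} nm box"
            )
        points[n_placed] = candidate
        n_placed += 1
    return points
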