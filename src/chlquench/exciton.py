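"""Frenkel exciton Hamiltonian for a chromophore pair (or small aggregate).

The excited states of an assembly of coupled chromophores are expanded in a
basis of single-site excitations |i>:

    H = sum_i E_i |i><i|  +  sum_{i != j} V_ij |i><j|

Site energies E_i come from embedded monomer calculations; the inter-site
coupling V_ij is the Coulomb interaction between the *transition charges*
of the two excitations (atomic point charges fitted to the transition
density, summing to ~0 per site).  Diagonalizing the real symmetric H gives
exciton states; the lowest eigenvalue is the pair excited-state energy used
to build excited-state free-energy surfaces.

A state whose coefficient-weighted vector sum of site transition dipoles
nearly cancels carries no oscillator strength ("dark"): an ideal cofacial
H-dimer has a dark lowest state at E - V.  Site-energy disorder larger than
|V| localizes states on single monomers, which is why thermally disordered
pairs rarely act as dark traps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import COULOMB_EV_ANG

__all__ = [
    "SiteExcitation",
    "ExcitonSystem",
    "ExcitonState",
    "transition_charge_coupling",
    "build_and_diagonalize",
    "classify_states",
    "dark_fraction",
]

#: Below this inter-atom distance two charge clouds are considered coincident.
MIN_CHARGE_SEPARATION_ANG = 0.1


@dataclass(frozen=True)
class SiteExcitation:
    """One chromophore's excitation: energy plus its transition charges.

    ``positions`` is (n_atoms, 3) in Angstrom, ``charges`` in elementary
    charges fitted to the transition density; they must sum to ~0 (a
    transition density carries no monopole).  The transition dipole is the
    first moment of the charges, in e*Angstrom.
    """

    site_index: int
    energy: float
    positions: np.ndarray
    charges: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        q = np.asarray(self.charges, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_atoms, 3)")
        if q.shape != (pos.shape[0],):
            raise ValueError("charges must be one per atom")
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(q)):
            raise ValueError("positions and charges must be finite")
        if abs(float(np.sum(q))) > 1e-6:
            raise ValueError(
                "transition charges must sum to ~0 "
                f"(|sum q| = {abs(float(np.sum(q))):.3g} e)"
            )
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", q)

    @property
    def transition_dipole(self) -> np.ndarray:
        """First moment of the transition charges, e*Angstrom."""
        return self.charges @ self.positions

    @property
    def dipole_strength(self) -> float:
        """|mu|^2 in e^2*Angstrom^2."""
        mu = self.transition_dipole
        return float(mu @ mu)


def transition_charge_coupling(
    site_a: SiteExcitation,
    site_b: SiteExcitation,
    screening: float = 1.0,
) -> float:
    """Coulomb coupling (eV) between the transition charges of two sites.

    V = f * sum_kl q_k q_l / (4 pi eps0 r_kl) with charges in e, distances
    in Angstrom; ``screening`` is an optional scalar attenuation (1 =
    unscreened vacuum Coulomb).  Raises if any inter-site atom pair is
    closer than 0.1 Angstrom (overlapping charge clouds make the point
    approximation meaningless).
    """
    r = cdist(site_a.positions, site_b.positions)
    if np.min(r) <= MIN_CHARGE_SEPARATION_ANG:
        raise ValueError(
            f"coincident charge positions across sites (min distance "
            f"{np.min(r):.3g} A)"
        )
    return float(
        screening
        * COULOMB_EV_ANG
        * np.sum(np.outer(site_a.charges, site_b.charges) / r)
    )


@dataclass(frozen=True)
class ExcitonSystem:
    """Sites plus a symmetric coupling matrix (zero diagonal, eV).

    If ``couplings`` is omitted it is computed from the transition charges;
    explicit values override (e.g. to inject disorder or literature V's).
    """

    sites: tuple[SiteExcitation, ...]
    couplings: np.ndarray | None = None
    screening: float = 1.0

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("need at least one site")
        n = len(self.sites)
        if self.couplings is None:
            v = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    v[i, j] = v[j, i] = transition_charge_coupling(
                        self.sites[i], self.sites[j], self.screening
                    )
            object.__setattr__(self, "couplings", v)
        else:
            v = np.asarray(self.couplings, dtype=float)
            if v.shape != (n, n):
                raise ValueError(f"couplings must be ({n}, {n})")
            if not np.allclose(v, v.T, atol=1e-12):
                raise ValueError("coupling matrix must be symmetric")
            if not np.allclose(np.diag(v), 0.0, atol=1e-12):
                raise ValueError("coupling matrix must have zero diagonal")
            object.__setattr__(self, "couplings", v)

    def hamiltonian(self) -> np.ndarray:
        h = np.array(self.couplings, dtype=float)
        np.fill_diagonal(h, [s.energy for s in self.sites])
        return h


@dataclass(frozen=True)
class ExcitonState:
    """One eigenstate: energy, site coefficients and derived descriptors.

    ``oscillator_proxy`` is |sum_i c_i mu_i|^2 relative to the mean monomer
    dipole strength (dimensionless; ~1 = one monomer's worth of brightness,
    ~0 = dark).  ``dominance`` is the largest squared coefficient (1 =
    fully localized).
    """

    energy: float
    coefficients: np.ndarray
    oscillator_proxy: float
    dominance: float

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if not np.isclose(float(c @ c), 1.0, atol=1e-8):
            raise ValueError("coefficients must be normalized")
        object.__setattr__(self, "coefficients", c)


def build_and_diagonalize(system: ExcitonSystem) -> list[ExcitonState]:
    """Eigenstates of the exciton Hamiltonian, sorted ascending in energy."""
    h = system.hamiltonian()
    evals, evecs = np.linalg.eigh(h)
    mus = np.array([s.transition_dipole for s in system.sites])
    mono = float(np.mean([s.dipole_strength for s in system.sites]))
    states = []
    for k in range(evals.size):
        c = evecs[:, k]
        collective = c @ mus
        proxy = float(collective @ collective) / mono if mono > 0 else 0.0
        states.append(
            ExcitonState(
                energy=float(evals[k]),
                coefficients=c,
                oscillator_proxy=proxy,
                dominance=float(np.max(c**2)),
            )
        )
    return states


def classify_states(
    states: list[ExcitonState],
    dark_threshold: float = 0.05,
    dominance_threshold: float = 0.8,
) -> list[dict]:
    """Label each state dark/bright and localized/delocalized.

    A state is *dark* when its oscillator proxy falls below
    ``dark_threshold`` (in units of the monomer strength) and *localized*
    when a single site carries more than ``dominance_threshold`` of the
    squared amplitude.
    """
    return [
        {
            "energy": s.energy,
            "oscillator_proxy": s.oscillator_proxy,
            "dominance": s.dominance,
            "dark": s.oscillator_proxy < dark_threshold,
            "localized": s.dominance > dominance_threshold,
        }
        for s in states
    ]


def dark_fraction(
    systems: list[ExcitonSystem],
    dark_threshold: float = 0.05,
    dominance_threshold: float = 0.8,
) -> dict:
    """Ensemble summary: how often the *lowest* exciton state is a dark trap.

    Returns the fractions of ensemble members whose lowest state is dark
    and whose lowest state is localized (monomer-dominated states keep
    their brightness and cannot trap excitations).
    """
    if not systems:
        raise ValueError("empty ensemble")
    n_dark = 0
    n_localized = 0
    for system in systems:
        lowest = build_and_diagonalize(system)[0]
        if lowest.oscillator_proxy < dark_threshold:
            n_dark += 1
        if lowest.dominance > dominance_threshold:
            n_localized += 1
    n = len(systems)
    return {
        "n_systems": n,
        "dark_lowest_fraction": n_dark / n,
        "localized_lowest_fraction": n_localized / n,
    }
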