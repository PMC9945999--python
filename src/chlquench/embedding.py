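"""Point-charge embedding arithmetic: ion charge correction and energy assembly.

The monomer-based QM/MM decomposition evaluates each chromophore quantum
mechanically inside a point-charge representation of everything else; the
total is assembled as

    E_total = sum_monomers E_qm_pol + sum_{group pairs} E_elec(group_i, group_j)

with every pair of charge groups counted exactly once and E_elec a direct
(non-periodic) Coulomb double sum.  Forcefield charges for a chlorophyll
*ion* are built from the neutral forcefield by shifting each atom by the
difference between the quantum charges of the ion and the neutral molecule:

    q'_i = q_i + (q_i_ion - q_i_neutral)

which transfers exactly the net ionic charge while keeping the neutral
forcefield's charge distribution as the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .constants import COULOMB_EV_ANG

__all__ = [
    "ChargeSet",
    "EnergyDecomposition",
    "correct_ion_charges",
    "point_charge_energy",
    "assemble_total_energy",
]

#: Atoms closer than this (Angstrom) are treated as coincident.
MIN_ATOM_SEPARATION_ANG = 1e-6


@dataclass(frozen=True)
class ChargeSet:
    """Named atomic partial charges (elementary charges) with provenance."""

    labels: tuple[str, ...]
    charges: np.ndarray
    provenance: str = "forcefield_neutral"

    def __post_init__(self) -> None:
        q = np.asarray(self.charges, dtype=float)
        if q.ndim != 1 or q.size != len(self.labels):
            raise ValueError("one charge per atom label required")
        if not np.all(np.isfinite(q)):
            raise ValueError("charges must be finite")
        object.__setattr__(self, "charges", q)

    @property
    def total_charge(self) -> float:
        return float(np.sum(self.charges))

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class EnergyDecomposition:
    """Assembled total energy and its components, eV."""

    e_qm_pol: float
    e_electrostatic: float
    e_total: float
    pair_energies: dict

    def __post_init__(self) -> None:
        if not np.isclose(
            self.e_total, self.e_qm_pol + self.e_electrostatic, atol=1e-10
        ):
            raise ValueError("e_total must equal e_qm_pol + e_electrostatic")


def correct_ion_charges(
    neutral_ff: ChargeSet, qm_ion: ChargeSet, qm_neutral: ChargeSet
) -> ChargeSet:
    """Forcefield charges for an ion: q'_i = q_i + (q_i_ion - q_i_neutral).

    All three sets must list the same atoms in the same order.  The result's
    total charge is total(neutral_ff) + [total(qm_ion) - total(qm_neutral)]
    exactly (the correction is a per-atom shift, so sums add).
    """
    if not (len(neutral_ff) == len(qm_ion) == len(qm_neutral)):
        raise ValueError(
            "atom-count mismatch: "
            f"{len(neutral_ff)}, {len(qm_ion)}, {len(qm_neutral)}"
        )
    if not (neutral_ff.labels == qm_ion.labels == qm_neutral.labels):
        raise ValueError("atom labels/order differ between charge sets")
    return ChargeSet(
        labels=neutral_ff.labels,
        charges=neutral_ff.charges + (qm_ion.charges - qm_neutral.charges),
        provenance="corrected",
    )


def point_charge_energy(
    charges_a: np.ndarray,
    positions_a: np.ndarray,
    charges_b: np.ndarray,
    positions_b: np.ndarray,
) -> float:
    """Direct Coulomb interaction energy (eV) between two charge groups.

    E = k sum_i sum_j q_i q_j / r_ij over all cross pairs, charges in e and
    positions in Angstrom; no periodic images.  Raises on coincident atoms.
    """
    qa = np.asarray(charges_a, dtype=float)
    qb = np.asarray(charges_b, dtype=float)
    pa = np.asarray(positions_a, dtype=float).reshape(len(qa), 3)
    pb = np.asarray(positions_b, dtype=float).reshape(len(qb), 3)
    r = cdist(pa, pb)
    if r.size and np.min(r) < MIN_ATOM_SEPARATION_ANG:
        raise ValueError(
            f"coincident atoms across groups (min distance {np.min(r):.3g} A)"
        )
    if r.size == 0:
        return 0.0
    return float(COULOMB_EV_ANG * np.sum(np.outer(qa, qb) / r))


def assemble_total_energy(
    e_qm_pol: Sequence[float],
    group_charges: Sequence[np.ndarray],
    group_positions: Sequence[np.ndarray],
    group_indices: Sequence[Sequence[int]] | None = None,
) -> EnergyDecomposition:
    """Assemble E_total = sum E_qm_pol + sum over group pairs of Coulomb energy.

    ``e_qm_pol`` holds one polarized-monomer QM energy per *monomer*; charge
    groups (monomers plus surroundings) contribute electrostatics through
    every unordered pair exactly once.  ``group_indices``, when given, are
    the atom indices of each group in a global numbering and must be
    disjoint (overlapping membership would double-count atoms).
    """
    if len(group_charges) != len(group_positions):
        raise ValueError("need positions for every charge group")
    if group_indices is not None:
        seen: set[int] = set()
        for g, idx in enumerate(group_indices):
            overlap = seen.intersection(idx)
            if overlap:
                raise ValueError(
                    f"overlapping group membership: atoms {sorted(overlap)} "
                    f"reappear in group {g}"
                )
            seen.update(idx)
    pair_energies: dict = {}
    e_elec = 0.0
    n = len(group_charges)
    for i in range(n):
        for j in range(i + 1, n):
            e_ij = point_charge_energy(
                group_charges[i],
                group_positions[i],
                group_charges[j],
                group_positions[j],
            )
            pair_energies[(i, j)] = e_ij
            e_elec += e_ij
    e_qm = float(np.sum(np.asarray(e_qm_pol, dtype=float)))
    return EnergyDecomposition(
        e_qm_pol=e_qm,
        e_electrostatic=e_elec,
        e_total=e_qm + e_elec,
        pair_energies=pair_energies,
    )
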