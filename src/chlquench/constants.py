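"""Physical constants, pinned in one place.

All energies in the package are electron-volts, distances in angstroms
(nanometres in the solution-statistics layer), temperatures in kelvin and
rates in ns^-1.  Every unit conversion flows through this table so that
reported rate constants are reproducible to the digit.
"""

#: Boltzmann constant, eV/K (CODATA).
KB_EV_PER_K: float = 8.617333e-5

#: Reduced Planck constant, eV*s (CODATA).
HBAR_EV_S: float = 6.582120e-16

#: Coulomb constant e^2/(4 pi eps0), eV*Angstrom per elementary charge pair.
COULOMB_EV_ANG: float = 14.3996

#: Hartree in eV.
HARTREE_EV: float = 27.2114

#: Bohr radius in Angstrom.
BOHR_ANG: float = 0.529177

#: Avogadro constant, mol^-1.
AVOGADRO: float = 6.02214076e23

#: Conversion: number density in nm^-3 per (mol dm^-3).
#: 1 mol dm^-3 = N_A molecules per 10^24 nm^3.
DENSITY_NM3_PER_MOLAR: float = AVOGADRO / 1.0e24

SECONDS_PER_NS: float = 1.0e-9


def thermal_energy(temperature: float) -> float:
    """k_B*T in eV for a temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_EV_PER_K * temperature
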