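"""Unit conventions and conversions.

Lengths are nanometres throughout (MD convention); PDB Angstroms are converted
on read/write.  Energies are reported in units of kT; spring constants are
stored in kJ/mol/nm^2 and converted with kT at the working temperature
(default 300 K, kT = 2.494 kJ/mol).
"""

KB_KJ_PER_MOL_K = 0.0083144626  # Boltzmann constant, kJ/mol/K
DEFAULT_TEMPERATURE = 300.0  # K
ANGSTROM_PER_NM = 10.0


def kt_kj_per_mol(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in kJ/mol at the given temperature (K)."""
    return KB_KJ_PER_MOL_K * temperature


def spring_kt_to_kj(k_kt_per_nm2: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a harmonic spring constant from kT/nm^2 to kJ/mol/nm^2."""
    return k_kt_per_nm2 * kt_kj_per_mol(temperature)


def spring_kj_to_kt(k_kj_per_nm2: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a harmonic spring constant from kJ/mol/nm^2 to kT/nm^2."""
    return k_kj_per_nm2 / kt_kj_per_mol(temperature)
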