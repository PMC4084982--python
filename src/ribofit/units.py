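"""Physical constants and unit conversions.

Internal unit system: kcal/mol (energy), Angstrom (length), picosecond
(time), amu (mass), Kelvin (temperature).
"""

import math

#: Boltzmann constant, kcal/mol/K
KB = 1.987204e-3

#: Avogadro's number, 1/mol
N_AVOGADRO = 6.02214076e23

#: Joules per kcal
J_PER_KCAL = 4184.0

#: Multiply a force in kcal/mol/A by this to get acceleration units of
#: amu * A / ps^2 (i.e. 1 kcal/mol = ~418.4 amu A^2/ps^2).
FORCE_TO_AMU_A_PS2 = J_PER_KCAL / (1.66053906660e-27 * 1e4 * N_AVOGADRO)


def pn_to_kcal_mol_angstrom(value: float) -> float:
    """Convert a force (pN) or force constant (pN/A) to kcal/mol/A units.

    1 pN acting over 1 A does 1e-12 N * 1e-10 m = 1e-22 J of work per
    molecule; multiplying by Avogadro's number and dividing by 4184 J/kcal
    gives 1.439e-2 kcal/mol — the standard single-molecule conversion.
    """
    if value < 0:
        raise ValueError("force constant must be non-negative")
    return value * 1e-22 * N_AVOGADRO / J_PER_KCAL


#: kcal/mol/A per pN (~1.439e-2)
PN_TO_KCAL_MOL_A = pn_to_kcal_mol_angstrom(1.0)


def thermal_energy(temperature: float) -> float:
    """k_B * T in kcal/mol."""
    return KB * temperature


assert math.isclose(PN_TO_KCAL_MOL_A, 1.439e-2, rel_tol=1e-3)
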