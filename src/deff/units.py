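"""Unit system and physical constants.

All energies are kcal/mol, all lengths are Angstrom, charges are in units of
the elementary charge and temperatures in Kelvin.  These choices are fixed
package-wide; no function accepts or returns any other unit.
"""

#: Coulomb constant, kcal * Angstrom / (mol * e^2).
COULOMB_CONSTANT = 332.06371

#: Molar gas constant, kcal / (mol * K).
GAS_CONSTANT = 1.9872e-3

#: 1 atm expressed in kcal / (mol * Angstrom^3), for PV work in NPT sampling.
ATM_TO_KCAL_PER_MOL_A3 = 1.4584e-5

#: Molar mass of water, g/mol (u).
WATER_MOLAR_MASS = 18.01528

#: Avogadro-derived conversion: (g/mol) / Angstrom^3 -> g/mL.
AMU_PER_A3_TO_G_PER_ML = 1.0 / 0.6022140857


def kT(temperature: float) -> float:
    """Thermal energy in kcal/mol at the given temperature in Kelvin."""
    return GAS_CONSTANT * temperature
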