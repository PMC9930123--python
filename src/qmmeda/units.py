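"""Unit conversions and physical constants.

All internal electronic-structure math is done in Hartree atomic units;
file formats and user-facing energies use Å, e and kcal/mol.
"""

HARTREE_TO_KCAL = 627.509474
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

#: Coulomb constant in kcal·Å/(mol·e²); equals HARTREE_TO_KCAL * BOHR_TO_ANGSTROM.
COULOMB_KCAL = 332.0637

#: 1 Debye in e·Å.
DEBYE_TO_E_ANGSTROM = 0.20819434
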