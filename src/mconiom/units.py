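"""Unit conventions and physical constants.

Internal units: Angstroem for coordinates, Hartree for energies (hence
Hartree/A for gradients and Hartree/A^2 for Hessians), amu for masses,
cm^-1 for vibrational frequencies, Kelvin for temperatures.  User-facing
energy reports are in kcal/mol.
"""

from __future__ import annotations

from scipy import constants as _c

HARTREE_TO_KCALMOL = 627.509474
HARTREE_TO_J = _c.physical_constants["Hartree energy"][0]
AMU_TO_KG = _c.atomic_mass
ANGSTROM_TO_M = 1e-10
KCAL_TO_J = 4184.0

PLANCK = _c.h
BOLTZMANN = _c.k
SPEED_OF_LIGHT = _c.c
AVOGADRO = _c.N_A
GAS_CONSTANT = _c.R
ATM_PA = float(_c.atm)

#: (Hartree / (A^2 amu)) -> angular-frequency-squared in s^-2
HESSIAN_EIGVAL_TO_OMEGA2 = HARTREE_TO_J / (AMU_TO_KG * ANGSTROM_TO_M**2)


def hartree_to_kcalmol(e: float) -> float:
    return e * HARTREE_TO_KCALMOL


def kcalmol_to_hartree(e: float) -> float:
    return e / HARTREE_TO_KCALMOL
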