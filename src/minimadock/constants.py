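"""Physical constants and unit conversions.

Internal convention: structures are in Å, energies in kcal/mol, masses in
amu, temperatures in K.  Partition functions are evaluated in SI units and
free energies converted back to kcal/mol.  All constants are CODATA-2018.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants plus the unit conversions the package needs."""

    #: Boltzmann constant, kcal/(mol*K)
    k_kcal: float = 1.987204259e-3
    #: Boltzmann constant, J/K (per molecule)
    k_J: float = 1.380649e-23
    #: Planck constant, J*s
    h: float = 6.62607015e-34
    #: reduced Planck constant, J*s
    hbar: float = 1.054571817e-34
    #: Avogadro constant, 1/mol
    N_A: float = 6.02214076e23
    #: Euler's number e
    euler_e: float = math.e
    #: atomic mass unit -> kg
    amu_to_kg: float = 1.66053906660e-27
    #: Å -> m
    angstrom_to_m: float = 1e-10
    #: kcal/mol -> J per molecule
    kcal_mol_to_J: float = 4184.0 / 6.02214076e23
    #: standard concentration 1 mol/L expressed in molecules/m^3
    standard_density: float = field(default=6.02214076e26)
    #: Coulomb prefactor q_i q_j / r  ->  kcal/mol with q in e, r in Å
    coulomb_kcal: float = 332.06371

    @property
    def hessian_to_si(self) -> float:
        """Convert mass-weighted Hessian eigenvalues from
        kcal/(mol*amu*Å^2) to SI angular-frequency-squared (s^-2)."""
        return self.kcal_mol_to_J / (self.amu_to_kg * self.angstrom_to_m**2)

    def kT(self, T: float) -> float:
        """Thermal energy at temperature *T*, kcal/mol."""
        return self.k_kcal * T


CONSTANTS = PhysicalConstants()
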