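"""Physical constants and unit conversions.

All internal quantities are in Hartree atomic units (lengths in bohr,
energies in hartree, momenta in bohr^-1, velocities in units where
hbar = m_e = e = 1).  User-facing energies are in eV, beam kinetic
energies in keV, collection angles in mrad.
"""

import math

#: hartree -> eV
HARTREE_EV = 27.211386

#: bohr -> angstrom
ANGSTROM_PER_BOHR = 0.52917721
BOHR_PER_ANGSTROM = 1.0 / ANGSTROM_PER_BOHR

#: speed of light in atomic units (1/alpha)
C_AU = 137.036

#: FWHM of a Gaussian divided by its standard deviation, 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def ev_to_hartree(energy_ev: float) -> float:
    return energy_ev / HARTREE_EV


def hartree_to_ev(energy_ha: float) -> float:
    return energy_ha * HARTREE_EV
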