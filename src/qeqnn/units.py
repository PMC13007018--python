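"""Internal unit system and physical constants.

Everything in the package works in eV / Angstrom / elementary-charge / fs /
amu / Kelvin.  Spectra are reported in cm^-1.  The Coulomb constant is fixed
at module load to the CODATA value ``KE = 14.399645`` eV*A/e^2; every
Coulombic expression in :mod:`qeqnn.electrostatics` carries this factor so
that charges in e and distances in Angstrom give energies in eV.
"""

from __future__ import annotations

import math

# Coulomb constant e^2/(4 pi eps0), eV * Angstrom / e^2 (CODATA)
KE = 14.399645

# Boltzmann constant, eV / K
KB = 8.617333262e-5

# Reduced Planck constant, eV * fs
HBAR = 0.6582119569

# 1 amu * (A/fs)^2 expressed in eV; multiplying a mass in amu by this factor
# yields a mass in eV*fs^2/A^2, so F[eV/A]/m gives accelerations in A/fs^2.
_AMU_KG = 1.66053906660e-27
_EV_J = 1.602176634e-19
AMU_TO_EVFS2_PER_A2 = _AMU_KG * 1e10 / _EV_J  # ~103.6427

# Speed of light, cm / fs (for wavenumber conversion)
C_CM_PER_FS = 2.99792458e-5

# Avogadro-free mass bookkeeping: atomic masses in amu
ATOMIC_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "O": 15.999,
    "N": 14.007,
    "C": 12.011,
    "Na": 22.990,
    "Cl": 35.45,
}

# amu/A^3 -> g/cm^3
AMU_PER_A3_TO_G_PER_CM3 = _AMU_KG * 1e3 / 1e-24  # = 1.66054

# 1 e*A in Debye
EA_TO_DEBYE = 1.0 / 0.2081943


def frequency_to_wavenumber(f_per_fs: float) -> float:
    """Convert an ordinary frequency in cycles/fs to cm^-1."""
    return f_per_fs / C_CM_PER_FS


def angular_frequency_to_wavenumber(omega_per_fs: float) -> float:
    """Convert an angular frequency in rad/fs to cm^-1."""
    return omega_per_fs / (2.0 * math.pi * C_CM_PER_FS)


def mass_of(symbol: str) -> float:
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise KeyError(f"no tabulated mass for element {symbol!r}") from None
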