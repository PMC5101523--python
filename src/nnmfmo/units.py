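"""Internal unit system and frequency conversions.

The model works in Å, kcal/mol and amu.  The derived time unit is
``sqrt(amu * Å² / (kcal/mol))`` ≈ 48.89 fs, so a 1 fs integrator step is
``1 / 48.89`` internal time units.  Angular frequencies in internal units
(rad per time unit) are reported as wavenumbers in cm⁻¹ throughout.
"""

import math

AVOGADRO = 6.02214076e23  # mol⁻¹
KCAL_J = 4184.0  # J per kcal (thermochemical calorie)
AMU_KG = 1.66053906660e-27  # kg
ANGSTROM_M = 1e-10  # m
C_CM_S = 2.99792458e10  # speed of light, cm/s

#: energy of 1 kcal/mol carried by a single particle, in J
ENERGY_UNIT_J = KCAL_J / AVOGADRO

#: internal time unit sqrt(amu Å² / (kcal/mol)) in seconds (≈ 4.889e-14 s)
TIME_UNIT_S = math.sqrt(AMU_KG * ANGSTROM_M**2 / ENERGY_UNIT_J)

#: internal time unit in femtoseconds (≈ 48.888)
TIME_UNIT_FS = TIME_UNIT_S * 1e15

#: wavenumber (cm⁻¹) of an angular frequency of 1 rad per internal time
#: unit, i.e. of sqrt(1 kcal/mol / (amu Å²)) (≈ 108.59 cm⁻¹)
OMEGA_UNIT_CM1 = 1.0 / (2.0 * math.pi * C_CM_S * TIME_UNIT_S)


def omega_to_cm1(omega):
    """Angular frequency in internal units (rad/time-unit) → cm⁻¹."""
    return omega * OMEGA_UNIT_CM1


def cm1_to_omega(nu):
    """Wavenumber in cm⁻¹ → angular frequency in internal units."""
    return nu / OMEGA_UNIT_CM1


def fs_to_internal(t_fs):
    """Time in femtoseconds → internal time units."""
    return t_fs / TIME_UNIT_FS


def hz_to_cm1(f_hz):
    """Ordinary (not angular) frequency in Hz → cm⁻¹."""
    return f_hz / C_CM_S
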