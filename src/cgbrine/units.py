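"""Internal unit system and conversion constants.

Internal units follow the common "real" MD convention:

* length   — Å
* time     — fs
* mass     — amu
* energy   — kcal/mol
* charge   — elementary charge e
* velocity — Å/fs

Pressures are reported in bar and tensions in mN/m at the boundaries;
everything below the reporting layer stays in the internal system.
"""

from __future__ import annotations

import math

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

#: Boltzmann constant, kcal/mol/K
KB = 0.001987204259

#: Molar gas constant, L·bar/(mol·K)  (used for van 't Hoff conversions)
R_L_BAR = 0.0831446262

#: 1 kcal/mol expressed in amu·Å²/fs².  Accelerations in Å/fs² are
#: F[kcal/mol/Å] * KCAL_MOL_TO_INTERNAL / m[amu].
KCAL_MOL_TO_INTERNAL = 4184.0 / N_AVOGADRO / 1.66053906660e-27 * 1e-30 / 1e-10 * 1e10
# evaluate explicitly to avoid silent unit slips: J/mol -> J -> amu Å²/fs²
KCAL_MOL_TO_INTERNAL = (4184.0 / N_AVOGADRO) / (1.66053906660e-27 * 1e-20 / 1e-30)

#: kinetic-energy prefactor: KE[kcal/mol] = 0.5 * MVV_TO_KCAL * m * v²
MVV_TO_KCAL = 1.0 / KCAL_MOL_TO_INTERNAL

#: 1 kcal/mol/Å³ in bar
KCAL_MOL_A3_TO_BAR = (4184.0 / N_AVOGADRO) / 1e-30 / 1e5

#: 1 bar·Å in mN/m  (surface-tension conversion)
BAR_A_TO_MN_M = 1e5 * 1e-10 * 1e3

#: 1 amu/Å³ in kg/m³
AMU_A3_TO_KG_M3 = 1.66053906660e-27 / 1e-30

#: Coulomb constant, kcal·Å/(mol·e²)
COULOMB_K = 332.0637

#: molar mass of water, g/mol
WATER_MOLAR_MASS = 18.01528

#: molarity of pure water at ~998 kg/m³, mol/L
WATER_MOLARITY = 998.0 / WATER_MOLAR_MASS


def kinetic_temperature(kinetic_energy: float, n_dof: int) -> float:
    """Instantaneous kinetic temperature in K from KE in kcal/mol."""
    if n_dof <= 0:
        raise ValueError("n_dof must be positive")
    return 2.0 * kinetic_energy / (n_dof * KB)


def thermal_sigma(temperature: float, mass: float) -> float:
    """Maxwell–Boltzmann velocity standard deviation (Å/fs) per component."""
    return math.sqrt(KB * temperature * KCAL_MOL_TO_INTERNAL / mass)
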