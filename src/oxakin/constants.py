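"""Physical constants on the unit system used throughout the package.

Internal energy unit is kcal/mol everywhere; lengths are Å, masses amu,
wavenumbers cm⁻¹, temperatures K, concentrations µM, times minutes
(s⁻¹ for rate constants).  Hartree is accepted on input only.
"""

from scipy import constants as _c

#: kcal/mol per hartree (conventional quantum-chemistry factor).
HARTREE_TO_KCAL = 627.509

#: J per (thermochemical) kcal.
KCAL_TO_J = 4184.0

#: Gas constant in kcal · mol⁻¹ · K⁻¹.
R_KCAL = _c.R / KCAL_TO_J

#: kcal/mol per cm⁻¹ of photon energy (h·c·Ñ·N_A), ≈ 2.85914e-3.
CM1_TO_KCAL = _c.h * _c.c * 100.0 * _c.N_A / KCAL_TO_J

#: Boltzmann constant, Planck constant (SI).
K_B = _c.k
PLANCK = _c.h

#: Speed of light in cm/s (wavenumber conversions).
C_CM = _c.c * 100.0

#: Avogadro constant.
N_A = _c.N_A

#: 1 atm in Pa; atomic mass unit in kg.
ATM = _c.atm
AMU = _c.atomic_mass

#: Molar volume of an ideal gas at 298.15 K, 1 atm, in litres — the
#: 1 atm → 1 M standard-state concentration ratio.
MOLAR_VOLUME_298 = _c.R * 298.15 / ATM * 1000.0  # 24.465 L/mol

#: ln(10)·R·T at 298.15 K in kcal/mol: free energy per pKa unit.
RT_LN10_298 = R_KCAL * 298.15 * 2.302585092994046
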