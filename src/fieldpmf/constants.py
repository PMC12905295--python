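"""Physical constants (CODATA 2018) and the unit conversions the package uses.

Everything downstream of Coulomb's law, the Eyring equation and the Stark
energy expression funnels through the handful of constants defined here, so
they are written out once, to full precision, with their derivations.
"""

import math

# CODATA 2018 exact / recommended values (SI)
ELEMENTARY_CHARGE = 1.602176634e-19  # C (exact)
BOLTZMANN = 1.380649e-23             # J/K (exact)
PLANCK = 6.62607015e-34              # J*s (exact)
AVOGADRO = 6.02214076e23             # 1/mol (exact)
SPEED_OF_LIGHT = 299792458.0         # m/s (exact)
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

#: Coulomb constant 1/(4 pi eps0), N m^2 / C^2
COULOMB_K_SI = 1.0 / (4.0 * math.pi * VACUUM_PERMITTIVITY)

#: thermochemical calorie
CAL_TO_J = 4.184
KCAL_TO_J = 4184.0

#: Gas constant in kcal/(mol K).  R = N_A * k_B / 4184.
R_KCAL = AVOGADRO * BOLTZMANN / KCAL_TO_J  # 1.987204e-3

# ---------------------------------------------------------------------------
# Electric field of a point charge, package units.
#
# A charge of q elementary charges at distance r angstrom produces a field
#   E = K_e * (q e) / (r * 1e-10 m)^2   [V/m]
# 1 MV/cm = 1e6 V / 1e-2 m = 1e8 V/m, so in MV/cm the prefactor is
#   COULOMB_FIELD_MV_CM = K_e * e * 1e20 / 1e8 = K_e * e * 1e12
# Numerically 1439.9645... MV/cm for a unit charge at 1 angstrom.
# ---------------------------------------------------------------------------
COULOMB_FIELD_MV_CM = COULOMB_K_SI * ELEMENTARY_CHARGE * 1e12

#: 1 debye in C m (definition: 1 D = 1e-21 / c C m^2 s^-1)
DEBYE_SI = 1e-21 / SPEED_OF_LIGHT

# ---------------------------------------------------------------------------
# Stark energy conversion: a dipole of 1 D in a field of 1 MV/cm stores
#   U = (1 D) * (1e8 V/m) = DEBYE_SI * 1e8 J per molecule
# which per mole, in kcal, is
#   DEBYE_MVCM_TO_KCAL = DEBYE_SI * 1e8 * N_A / 4184  ~ 0.048 kcal/mol
# ---------------------------------------------------------------------------
DEBYE_MVCM_TO_KCAL = DEBYE_SI * 1e8 * AVOGADRO / KCAL_TO_J

# ---------------------------------------------------------------------------
# Molecular-dynamics unit bridge: with energies in kcal/mol, masses in amu,
# lengths in angstrom and times in ps,
#   1 kcal/mol = 4184 J/mol = 4184 / (N_A * 1.66054e-27 kg) * (amu) ...
# working it through, 1 kcal/mol = 418.4 amu A^2 / ps^2 (to 5 figures using
# the exact amu below).
# ---------------------------------------------------------------------------
AMU_KG = 1.66053906660e-27
KCAL_PER_MOL_TO_AMU_A2_PS2 = KCAL_TO_J / AVOGADRO / AMU_KG / 1e-20 * 1e-24
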