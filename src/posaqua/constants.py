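"""Physical constants and unit conversions.

All quantum-chemical internals work in hartree/bohr; the classical liquid
code works in kJ/mol and Å.  Every conversion used anywhere in the package
is pinned here, derived from CODATA-2018 base values where applicable.
"""

import math

# --- CODATA-2018 base values (SI) ---
BOHR_RADIUS_M = 0.529177210903e-10
CLASSICAL_ELECTRON_RADIUS_M = 2.8179403262e-15
SPEED_OF_LIGHT_M_S = 299792458.0
AVOGADRO = 6.02214076e23
BOLTZMANN_J_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602176634e-19
EPSILON0 = 8.8541878128e-12
HARTREE_J = 4.3597447222071e-18

# --- length ---
BOHR_PER_ANGSTROM = 1.0e-10 / BOHR_RADIUS_M          # ≈ 1.8897
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

# --- energy ---
HARTREE_TO_EV = HARTREE_J / ELEMENTARY_CHARGE_C       # 27.2114...
HARTREE_TO_MEV = HARTREE_TO_EV * 1000.0
HARTREE_TO_KJMOL = HARTREE_J * AVOGADRO / 1000.0
KCAL_TO_KJ = 4.184

# --- classical force-field units ---
# Coulomb constant e^2/(4 pi eps0) in kJ mol^-1 Å
COULOMB_KJ_A = (ELEMENTARY_CHARGE_C**2 / (4.0 * math.pi * EPSILON0)
                * AVOGADRO / 1000.0 * 1.0e10)
KB_KJMOL = BOLTZMANN_J_K * AVOGADRO / 1000.0          # 0.008314...
ATM_TO_KJMOL_A3 = 101325.0 * 1.0e-30 * AVOGADRO / 1000.0

# --- dipole ---
# 1 e·Å in Debye; 1 D = 1e-21/c C m
DEBYE_C_M = 1.0e-21 / SPEED_OF_LIGHT_M_S
EA_TO_DEBYE = ELEMENTARY_CHARGE_C * 1.0e-10 / DEBYE_C_M    # 4.8032...
AU_TO_DEBYE = ELEMENTARY_CHARGE_C * BOHR_RADIUS_M / DEBYE_C_M  # 2.5417...


def annihilation_rate_constant_ns() -> float:
    """Spin-averaged two-photon rate constant pi*r0^2*c per unit contact
    density, expressed in ns^-1 per atomic unit of density (bohr^-3).

    Re-derived from CODATA values at call time rather than hard-coded;
    evaluates to ≈ 50.47 ns^-1.
    """
    rate_si = (math.pi * CLASSICAL_ELECTRON_RADIUS_M**2 * SPEED_OF_LIGHT_M_S
               / BOHR_RADIUS_M**3)          # s^-1 per a.u. density
    return rate_si * 1.0e-9


# atomic masses (g/mol) for density bookkeeping
ATOMIC_MASS = {
    "H": 1.00794, "C": 12.011, "N": 14.0067, "O": 15.9994, "Li": 6.941,
}

# nuclear charges
ATOMIC_NUMBER = {"H": 1, "Li": 3, "C": 6, "N": 7, "O": 8}

# Bragg-Slater radii (Å) for multicenter grid partitioning
BRAGG_RADII_A = {"H": 0.35, "Li": 1.45, "C": 0.70, "N": 0.65, "O": 0.60}

# vdW radii (Å) for ESP-fit point selection
VDW_RADII_A = {"H": 1.20, "Li": 1.82, "C": 1.70, "N": 1.55, "O": 1.52}
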