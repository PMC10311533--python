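"""Physical constants and lanthanide single-ion data.

Internal unit conventions used across the package:

* lengths in Å, time in fs, temperature in K;
* crystal-field energies in cm⁻¹;
* magnetic susceptibility either as cgs molar (cm³ mol⁻¹, the convention of
  quantum-chemistry outputs) or as SI per-molecule volume (m³), with the
  conversion χ_SI = χ_cgs · 4π×10⁻⁶ / N_A.
"""

import math

# CODATA 2018
MU_B_J_PER_T = 9.2740100783e-24      # Bohr magneton, J T⁻¹
K_B_J_PER_K = 1.380649e-23           # Boltzmann constant, J K⁻¹
N_AVOGADRO = 6.02214076e23           # mol⁻¹
K_B_CM_PER_K = 0.6950348004          # k_B/(hc), cm⁻¹ K⁻¹
MU_B_CM_PER_T = 0.4668644778         # μ_B/(hc), cm⁻¹ T⁻¹
CM1_TO_J = 1.986445857e-23           # hc·(1 cm⁻¹), J
BOHR_RADIUS_ANGSTROM = 0.529177210903

# e²/(4πε₀), expressed in cm⁻¹·Å (14.399645 eV·Å × 8065.54394 cm⁻¹/eV)
E2_OVER_4PI_EPS0_CM_ANGSTROM = 14.399645478 * 8065.543937

# χ(cgs molar, cm³ mol⁻¹) → χ(SI per molecule, m³)
CHI_CGS_MOLAR_TO_SI_MOLECULE = 4.0 * math.pi * 1e-6 / N_AVOGADRO

# Magnetizability ξ = -∂²F/∂B² (J T⁻²) → cgs molar susceptibility (cm³ mol⁻¹):
# χ_cgs = μ0·N_A·ξ · 10⁶/(4π) = 0.1·N_A·ξ
XI_SI_TO_CHI_CGS_MOLAR = 0.1 * N_AVOGADRO

# Ground-multiplet quantum numbers (J, g_J) of selected Ln(III) ions
LN_GROUND_MULTIPLET = {
    "Ce": (2.5, 6.0 / 7.0),
    "Pr": (4.0, 4.0 / 5.0),
    "Nd": (4.5, 8.0 / 11.0),
    "Sm": (2.5, 2.0 / 7.0),
    "Tb": (6.0, 3.0 / 2.0),
    "Dy": (7.5, 4.0 / 3.0),
    "Ho": (8.0, 5.0 / 4.0),
    "Er": (7.5, 6.0 / 5.0),
    "Tm": (6.0, 7.0 / 6.0),
    "Yb": (3.5, 8.0 / 7.0),
}

# Bleaney constants C_J, conventional normalization C_Dy = -100
BLEANEY_CJ = {
    "Ce": -6.3,
    "Pr": -11.0,
    "Nd": -4.2,
    "Sm": -0.7,
    "Eu": 4.0,
    "Tb": -86.0,
    "Dy": -100.0,
    "Ho": -39.0,
    "Er": 33.0,
    "Tm": 53.0,
    "Yb": 22.0,
}

# Dy(III) Stevens operator-equivalent factors θ_k (α, β, γ)
DY_STEVENS_THETA = {
    2: -2.0 / (3**2 * 5 * 7),
    4: -8.0 / (3**3 * 5 * 7 * 11 * 13),
    6: 4.0 / (3**3 * 7 * 11**2 * 13**2),
}

# Dy(III) radial expectation values ⟨r^k⟩ in units of a0^k (Freeman–Watson)
DY_RADIAL_EXPECTATION_A0 = {2: 0.726, 4: 1.322, 6: 5.102}
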