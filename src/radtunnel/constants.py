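"""Physical constants and unit conversions.

All constants are fixed to 7 significant digits so results reproduce
bit-for-bit at double precision across platforms.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3

#: hc/k_B in cm K: u = (HC_OVER_KB * nu_tilde) / T for nu_tilde in cm^-1.
HC_OVER_KB = 1.438777

#: 1 kcal mol^-1 expressed in cm^-1.
KCAL_TO_CM = 349.755

#: 1 hartree in kcal mol^-1.
HARTREE_TO_KCAL = 627.5095

#: 1 hartree in cm^-1 (= HARTREE_TO_KCAL * KCAL_TO_CM to working precision).
HARTREE_TO_CM = 219474.6

#: 1 bohr in angstrom.
BOHR_TO_ANG = 0.5291772

#: 1 unified atomic mass unit in electron masses.
AMU_TO_ME = 1822.888

#: Mass of the transferring protium atom, u.
MASS_H = 1.00783

#: Mass of deuterium, u.
MASS_D = 2.0141
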