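"""Physical constants and atomic masses used across the package.

Atomic masses are IUPAC 2021 conventional values; physical constants are
CODATA 2018 (exact, post-SI-redefinition where applicable).
"""

BOLTZMANN = 1.380649e-23
"""Boltzmann constant k_B, J/K (exact)."""

DEFAULT_TEMPERATURE_K = 295.15
"""Default absolute temperature, K (22 degC, the nucleation-experiment bath)."""

GYROMAGNETIC_1H = 26.75e7
"""Proton gyromagnetic ratio, rad T^-1 s^-1."""

GAUSS_PER_CM_TO_T_PER_M = 0.01
"""Gradient unit conversion: 1 G/cm = 0.01 T/m."""

# atomic / molecular masses, g/mol
MASS_S = 32.06
MASS_N = 14.007
MASS_C = 12.011
MASS_H = 1.008
MASS_O = 15.999

MASS_GLUCOSAMINE_MONOMER = 161.156
"""Anhydro-glucosamine residue C6H11NO4 (deacetylated chitosan monomer)."""

MASS_ACETYL_INCREMENT = 42.037
"""Mass added per acetyl substitution (C2H2O)."""

MASS_SULFATE_INCREMENT = 80.06
"""Mass added per -SO3 substitution (SO3, H retained on the heteroatom)."""

MASS_GLUTARALDEHYDE = 100.117
"""Glutaraldehyde C5H8O2, g/mol (cross-linker)."""

DAVIES_A_25C = 0.5092
"""Debye-Huckel/Davies A parameter at 25 degC, (mol/L)^-1/2."""
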