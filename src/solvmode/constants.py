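"""Physical constants (CODATA 2018) and unit conversions.

Every module takes its constants from here so that thermochemical
quantities are reproducible to the last printed digit.
"""

# SI exact / CODATA-2018 values
PLANCK_H = 6.62607015e-34  # J s
BOLTZMANN_KB = 1.380649e-23  # J / K
AVOGADRO_NA = 6.02214076e23  # 1 / mol
GAS_CONSTANT_R = BOLTZMANN_KB * AVOGADRO_NA  # 8.31446... J / (mol K)
SPEED_OF_LIGHT = 2.99792458e8  # m / s
SPEED_OF_LIGHT_CM = SPEED_OF_LIGHT * 100.0  # cm / s

AMU_KG = 1.66053906660e-27  # kg
HARTREE_J = 4.3597447222071e-18  # J
HARTREE_KJ_PER_MOL = HARTREE_J * AVOGADRO_NA / 1000.0  # 2625.4996... kJ/mol
BOHR_ANGSTROM = 0.529177210903  # Angstrom

ATM_PA = 101325.0  # Pa
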