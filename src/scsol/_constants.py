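"""Physical constants and default component properties.

All values are standard reference data. Model-internal unit conventions are
documented where they matter (see docs/methods.md): the density models take
T in K, rho in kg/m3 and P in MPa (bar only for the two P_ref-bearing forms),
while the equation-of-state module works in SI (Pa, m3, mol, K).
"""

R_GAS = 8.314  # J / (mol K)
P_ATM = 101_325.0  # Pa
MPA_TO_BAR = 10.0

M_CO2 = 44.01  # g/mol

# CO2 critical constants (standard reference values)
CO2_TC = 304.13  # K
CO2_PC = 7.377e6  # Pa
CO2_OMEGA = 0.225

# Methyldopa physical properties (solute of the packaged dataset)
METHYLDOPA_MW = 211.21  # g/mol
METHYLDOPA_TB = 844.5  # K, boiling temperature (estimated)
METHYLDOPA_TC = 1177.3  # K
METHYLDOPA_PC = 2.45e6  # Pa
METHYLDOPA_OMEGA = 0.558  # Ambrose-Walton estimate
METHYLDOPA_VS = 335.4  # cm3/mol, solid molar volume
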