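"""Decompose the dissolution enthalpy from the binary correlations.

The 1/T coefficient of the Chrastil model gives the total enthalpy of the
dissolution process (vaporization + solvation) via a van't Hoff relation;
the 1/T coefficient of the Bartle model, which works at a reference density,
isolates the vaporization enthalpy.  Their difference is the solvation
enthalpy of the drug in supercritical CO2.
"""

from scsol import OptimizerConfig, builtin_dataset, enthalpy_report, fit_model

binary = builtin_dataset("binary")
cfg = OptimizerConfig(seed=1)
chrastil = fit_model("chrastil", binary, cfg)
bartle = fit_model("bartle", binary, cfg)
report = enthalpy_report(chrastil, bartle)

print(f"Total enthalpy (Chrastil a1):       {report.total_kj_mol:7.2f} kJ/mol")
print(f"Vaporization enthalpy (Bartle a1):  {report.vaporization_kj_mol:7.2f} kJ/mol")
print(f"Solvation enthalpy (difference):    {report.solvation_kj_mol:7.2f} kJ/mol")
print(
    "\nA negative solvation enthalpy means solute-CO2 interactions are "
    "exothermic; the positive total reflects the dominant sublimation cost."
)
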