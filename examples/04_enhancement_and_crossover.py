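"""Quantify what ethanol does to methyldopa solubility: enhancement factors
at matched conditions and the shift of the crossover pressure.

The enhancement factor e = y2'/y2 compares ternary and binary mole fractions
at the same (T, P).  The crossover pressure is where solubility isotherms
intersect: below it, heating reduces solubility (density effect dominates);
above it, heating increases solubility (vapour-pressure effect dominates).
Polar cosolvents shift the crossover to lower pressure.
"""

from scsol import builtin_dataset, crossover_pressure, enhancement_factors

binary = builtin_dataset("binary")
for label in ("ethanol-1%", "ethanol-3%"):
    ternary = builtin_dataset(label)
    table = enhancement_factors(binary, ternary)
    best = table.loc[table.enhancement.idxmax()]
    print(
        f"{label}: e ranges {table.enhancement.min():.2f} - "
        f"{table.enhancement.max():.2f}; maximum at "
        f"{best.temperature:.0f} K, {best.pressure:.0f} MPa"
    )

print()
print(f"binary crossover:      {crossover_pressure(binary).aggregate_mpa:.1f} MPa")
for label in ("ethanol-1%", "ethanol-3%"):
    agg = crossover_pressure(builtin_dataset(label)).aggregate_mpa
    print(f"{label + ' crossover:':22s} {agg:.1f} MPa")
print(
    "\nThe largest enhancement (about 16-fold at 3 mol% ethanol) occurs at "
    "the lowest-density condition, and ethanol pulls the crossover from "
    "about 17 MPa down to about 14.5 MPa."
)
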