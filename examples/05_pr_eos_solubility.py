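"""Model the binary solubility with the Peng-Robinson equation of state.

The solid-fluid equilibrium condition y2 = (Psub/P)(1/phi2) exp(v2s(P-Psub)/RT)
is solved with PR fugacity coefficients under two-parameter van der Waals
mixing; the binary interaction corrections (k12, l12) are regressed against
the 28 measured points.  The solute sublimation pressure comes from a
boiling-point (modified-Grain) estimate, the dominant uncertainty of the
whole approach.
"""

import numpy as np

from scsol import OptimizerConfig, builtin_dataset
from scsol.pr_eos import fit_interaction_params, solubility_eos_grid, sublimation_pressure

binary = builtin_dataset("binary")
print(f"sublimation pressure estimate: {sublimation_pressure(308.0):.2e} Pa at 308 K, "
      f"{sublimation_pressure(338.0):.2e} Pa at 338 K")

cfg = OptimizerConfig(seed=1, n_restarts=4, steps_per_temp=50, n_temps=60)
inter, metrics = fit_interaction_params(binary, config=cfg)
print(f"fitted interaction parameters: k12 = {inter.k12:.3f}, l12 = {inter.l12:.3f}")
print(f"AARD = {metrics.aard_percent:.2f}%, R2 = {metrics.r_squared:.3f} over "
      f"{metrics.n_points} points")

y = solubility_eos_grid(binary.temperature, binary.pressure * 1e6, interaction=inter)
worst = int(np.argmax(np.abs(y - binary.mole_fraction) / binary.mole_fraction))
rec = binary.records[worst]
print(f"worst point: {rec.temperature:.0f} K, {rec.pressure:.0f} MPa "
      f"(predicted {y[worst]:.2e} vs measured {rec.mole_fraction:.2e})")
print(
    "\nWith one global (k12, l12) the EoS correlates the table to ~15%; "
    "per-isotherm parameters (scope='per-isotherm') reach ~8.5% because the "
    "estimated sublimation-pressure slope is steeper than the data imply."
)
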