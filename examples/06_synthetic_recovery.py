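"""Validate the fitting stack by parameter recovery on synthetic data.

Datasets are generated from the Gonzalez model with known parameters on the
study's (T, P, rho) grid, with 4% multiplicative lognormal noise mimicking
the assay's replicate precision, then refit.  Bias and RMSE per parameter
show which coefficients the experimental design actually pins down.
"""

from scsol import recovery_experiment

truth = (3.27, 0.955, -4547.2, -12.075)
report = recovery_experiment(
    "gonzalez", truth, noise_rsd=0.04, n_trials=10, seed=1,
    cosolvent_levels=(0.01, 0.03),
)

print("true parameters: ", truth)
print("bias:            ", [f"{v:+.3g}" for v in report["bias"]])
print("rmse:            ", [f"{v:.3g}" for v in report["rmse"]])
print(f"median refit AARD: {report['median_aard_percent']:.2f}%")
print(
    "\nThe median AARD of a correctly specified model tracks the injected "
    "noise level (about 3% here); parameters multiplying near-constant "
    "regressors (the intercept and 1/T over a 30 K window) carry most of "
    "the recovery uncertainty."
)
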