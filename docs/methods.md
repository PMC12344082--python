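# Methods

## Data model and units

A `SolubilityRecord` holds one equilibrium observation: temperature (K),
pressure (MPa), pure-CO₂ density (kg/m³), solute mole fraction (y₂ binary,
y₂′ ternary), cosolvent mole fraction y₃ and the replicate standard
deviation. Collections are sorted into isotherms with strictly increasing
pressures and validated on construction (positive T, P, ρ; y in (0,1)).

Two deliberate data choices:

- **Ternary densities.** The ternary tables report no density, and the
  density increase from 1–3 mol% ethanol is known only qualitatively. Every
  ternary record therefore carries the pure-CO₂ (NIST) density at its
  (T, P). All six ternary models use ρ₁ as *solvent* density, so this is
  consistent; it does mean ternary parameters absorb any small real density
  shift.
- **Scale.** Mole fractions are stored as plain values (2.38×10⁻⁵), never on
  the printed ×10⁴ scale; the loader takes `mole_fraction_scale` for tables
  stored scaled. Replicate SDs are carried but unweighted by default
  (`OptimizerConfig(weight_by_sd=True)` enables 1/sd² weighting).

Unit conventions inside model formulas (parameters are convention-dependent
and meaningless without them): T in K, ρ₁ in kg/m³; P in bar with
P_ref = 1 bar for the two pressure-referenced forms (Bartle, MST), P in MPa
everywhere else; Bartle's ρ_ref = 700 kg/m³. These were cross-checked by
evaluating published parameter vectors for the González and
Soltani–Mazloumi models against the measured data (agreement to a few
percent confirms MPa in Eqs. of the Soltani/Jouyban/Sodeifian family).
The PR-EoS module works in SI (Pa, m³, mol) and converts at its boundary.

## Density-model fitting

All ten models are linear in their parameters after a fixed transform of the
response (ln y, ln S, or T·ln(yP/P_ref)). The fitter exploits this twice:

1. an ordinary-least-squares solution in the linearised coordinates seeds
   the optimiser and serves as an independent oracle (the final log-space
   SSE may never exceed it — enforced by test);
2. the self-consistency plot of each model is its linearised rearrangement:
   transformed response minus all non-density terms against the density
   regressor, on which noise-free model data fall on an exact line.

**Objective.** The default loss is least squares on the model's response
(`sse`; g/L for Chrastil, mole fraction otherwise), with `aard` and
`sse_log` as alternatives. The choice is empirical model-archaeology: the
packaged study's reported statistics are only consistent with a
least-squares loss. A fully converged AARD minimiser *undercuts* several of
the reported AARDs (Kumar–Johnston 6.7% vs the reported 8.5% "best model"),
which is impossible if AARD had been the loss, while the least-squares
optimum reproduces the reported AARD, R² and enthalpy values closely. AARD
and R² are reported as metrics of every fit regardless of the loss; the SSE
entering AICc is always computed in mole-fraction space so that Chrastil is
rankable against the rest.

**Optimiser.** Seeded multistart simulated annealing: 8 restarts (restart 0
from the OLS seed), geometric cooling with factor 0.95 over 120 temperature
levels, 200 Metropolis steps per level, Gaussian proposals scaled to the
bound width and the current temperature, followed by a Nelder–Mead polish of
the best candidate (and of the OLS seed). Auto-generated bounds span
θ_OLS ± (3|θ_OLS| + 1) and widen once (×10) on boundary convergence;
user-supplied bounds are hard. Identical (data, config, seed) give identical
results; restart tie-breaks go to the lowest objective, then the lowest
restart index.

**AICc convention.** AICc = n ln(SSE/n) + 2k + 2k(k+1)/(n−k−1) with k the
number of adjustable parameters — the Gaussian-likelihood form. Published
AICc values for this dataset use an unstated convention, so AICc is used
here for *ranking*, not cross-study comparison.

**A structural caveat: Garlapati–Madras.** The seven-parameter form contains
ln ρ₁, ln T, ln y₃ *and* ln(y₃ρ₁T) = ln y₃ + ln ρ₁ + ln T as regressors, so
its design matrix is exactly rank-deficient: individual parameters are not
identifiable, only the six combinations (a₀, a₂, a₃, a₁+a₆, a₄+a₆, a₅+a₆).
Predictions, AARD and R² are unaffected (the optimum is a flat valley);
recovery tests for this model assert the identifiable combinations.

## Enthalpies

From a fitted Chrastil model, ΔH_total = −a₁·R (a₁ being the 1/T
coefficient, in K); from Bartle, ΔH_vap = −a₁·R; ΔH_sol is their exact
difference, no independent information. On the packaged data this gives
+34.3, +53.2 and −18.9 kJ/mol: dissolution is dominated by the
sublimation-like cost, solvation is exothermic.

## Cosolvent analysis

The enhancement factor is the plain ratio e = y₂′/y₂ at matched (T, P) —
the convention of the tabulated data (some sources print the same quantity
×100). Crossover pressures are estimated deterministically: for each pair of
isotherms, the intersection of the piecewise-linear interpolants of ln y vs
P on their common pressure grid; a pair contributes its median crossing with
the bracketing grid interval, and the aggregate is the median over pairs
(pairs that never cross are reported but excluded). On the packaged data:
binary 16.8 MPa, ethanol levels ≈14.5 MPa.

## Peng–Robinson equation of state

Standard PR with κ(ω) = 0.37464 + 1.54226ω − 0.26992ω², quadratic vdW2
mixing a_ij = √(a_i a_j)(1−k_ij), b_ij = ½(b_i+b_j)(1−l_ij). Because b is
quadratic in composition, the fugacity coefficient uses the full
∂(nb_m)/∂n_i = 2Σ_j x_j b_ij − b_m term; the closed form is verified against
central-difference differentiation of the residual Helmholtz energy to
better than six significant figures, plus a Gibbs–Duhem spot-check. Cubic
roots are solved in closed form (vectorised Cardano/trigonometric); when
several roots satisfy v > b the one of least residual Gibbs energy is taken,
which at these dense supercritical conditions is the small-volume root and
keeps y₂(P) continuous (verified by a resolution-refinement jump test).

Solute properties: T_b = 844.5 K, T_c = 1177.3 K, P_c = 2.45 MPa, ω = 0.558,
v₂ˢ = 335.4 cm³/mol. φ₂ˢᵃᵗ = 1: at sub-pascal sublimation pressures the
saturated-vapour nonideality is negligible. The solubility equation is
solved by fixed-point iteration from y₂ = 10⁻⁵ (relative tolerance 10⁻¹⁰,
φ₂ re-evaluated at each iterate); at near-infinite dilution it converges in
a handful of iterations.

**Sublimation pressure** is the weak point of any such calculation for a
compound with no measured vapour-pressure data. The default is the
modified-Grain boiling-point correlation
ln(P/P_atm) = (ΔS_b/R)[1 − (3−2T_pt)^m/T_pt − 2m(3−2T_pt)^(m−1) ln T_pt],
T_pt = T/T_b, m = 0.4133 − 0.2575 T_pt, with ΔS_b = 86.9 J/(mol·K) (a
strongly associating solid; the Fishtine form K_F(8.75 + R ln T_b) can be
passed via `entropy_of_boiling`, or any estimator injected through
`SolutePhysProps.sublimation_pressure_override`). This choice dominates the
achievable fit: with the default estimator the globally fitted (k₁₂, l₁₂)
reach AARD ≈ 15.4% over the 28 binary points, limited by the estimator's
temperature slope (a free two-parameter sublimation law reaches ~7%);
per-isotherm (k₁₂, l₁₂) — `scope="per-isotherm"` — reach a pooled 8.5%
with k₁₂ falling from 0.26 to 0.14 between 308 and 338 K. Both modes are
first-class because published correlations of this kind are reported under
either convention, frequently without saying which.

## Synthetic data and what passing tests mean

The generator draws mole fractions from a chosen model surface on the
experimental grid (default: the packaged 4×7 grid with its densities), with
multiplicative lognormal noise — `noise_rsd` defaults to 0.04, the
replicate precision of the assay (RSD < 4%), and multiplicative noise keeps
y > 0 across the two decades the data span. Three replicates per condition
are averaged into the stored value and populate the SD column, mirroring
the triplicate measurements. `recovery_experiment` wraps seeded
generate-and-refit loops and reports per-parameter bias/RMSE and the AARD
distribution.

The generator reproduces the *statistical* structure (grid, noise level,
positivity, replicate SD), not systematic features of real measurements:
density errors, equilibration failures, depressurisation losses or
temperature-correlated bias. Recovery tests therefore demonstrate that the
estimation machinery is correct and that the experimental design identifies
the parameters it identifies — not that any model is "true" for real data.
Design-based standard errors (computed from the linearised design under the
noise model) decide which parameters count as well-conditioned in the
recovery tests; over a 30 K window the intercept-like and 1/T-like
regressors are nearly collinear, so those coefficients are intrinsically
soft even when predictions are excellent.

## Numerical details and edge cases

- All randomness flows from integer seeds through `numpy` SeedSequence
  spawning; CLI artifacts embed the seed, package version and an input
  digest.
- Fits require n ≥ k + 2 points; AICc requires n > k + 1; R² refuses
  constant observations; AARD refuses zeros.
- Off-grid density queries raise, naming the nearest grid point, unless
  bilinear interpolation is explicitly enabled.
- Ternary models raise on y₃ = 0 rather than return −∞.
- Model fits that fail inside `fit_all` are reported per model and do not
  poison the remaining fits.
- Problem sizes used by the shipped analysis: 28 binary and 56 pooled
  ternary records per fit; the acceptance script's full rerun (10 density
  fits + the EoS regression) completes in about a minute on one CPU.

## Known limitations

- The EoS stage is binary-only (CO₂ + drug); a ternary EoS with
  composition-dependent cosolvent interactions is out of scope.
- No parameter-uncertainty reporting on the study fits (the source reports
  none); the synthetic module is the intended route to uncertainty
  statements.
- The sublimation-pressure estimate is an order-of-magnitude tool; absolute
  k₁₂/l₁₂ values are only meaningful jointly with the estimator used.
- Printed reference values from the source study carry the convergence
  quality of its (unstated-loss, unstated-schedule) optimiser; where our
  converged optima disagree by more than the stochastic tolerance the
  discrepancy is documented rather than tuned away.
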