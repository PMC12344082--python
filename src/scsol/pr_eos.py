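"""Peng-Robinson equation of state with two-parameter van der Waals mixing.

Solid-fluid equilibrium for a heavy solute (2) in supercritical CO2 (1):

    y2 = (P2_sub / P) * (phi2_sat / phi2) * exp(v2s (P - P2_sub) / RT)

with the solute fugacity coefficient phi2 from the PR EoS under quadratic
(vdW2) mixing rules a_ij = sqrt(a_i a_j)(1 - k_ij), b_ij = (b_i + b_j)/2
(1 - l_ij).  The solute sublimation pressure is estimated from its boiling
temperature by a modified-Grain correlation (overridable through
``SolutePhysProps.sublimation_pressure_override``), and phi2_sat is taken as
unity: at sub-pascal sublimation pressures the saturated-vapour correction is
indistinguishable from 1.

Everything in this module is in SI units (K, Pa, m3, mol); collection-facing
helpers convert from the dataset's MPa at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._constants import CO2_OMEGA, CO2_PC, CO2_TC, M_CO2, P_ATM, R_GAS
from .dataset import IsothermCollection, METHYLDOPA, SolutePhysProps
from .errors import ConfigError, ConvergenceError, ValidationError

__all__ = [
    "EoSComponent",
    "InteractionParams",
    "EoSState",
    "CO2_COMPONENT",
    "component_from_props",
    "kappa",
    "pure_params",
    "mixture_params",
    "solve_compressibility",
    "fugacity_coefficient",
    "fugacity_coefficient_numerical",
    "sublimation_pressure",
    "solubility_eos",
    "solubility_eos_grid",
    "fit_interaction_params",
]

_SQRT2 = np.sqrt(2.0)
_GRAIN_DSB = 86.9  # J/(mol K), boiling entropy of the modified-Grain estimate


@dataclass(frozen=True)
class EoSComponent:
    critical_temperature: float  # K
    critical_pressure: float  # Pa
    acentric_factor: float
    molar_mass: float  # g/mol

    def __post_init__(self) -> None:
        for name in ("critical_temperature", "critical_pressure", "molar_mass"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")


CO2_COMPONENT = EoSComponent(CO2_TC, CO2_PC, CO2_OMEGA, M_CO2)


def component_from_props(props: SolutePhysProps) -> EoSComponent:
    return EoSComponent(
        critical_temperature=props.critical_temperature,
        critical_pressure=props.critical_pressure,
        acentric_factor=props.acentric_factor,
        molar_mass=props.molar_mass,
    )


@dataclass(frozen=True)
class InteractionParams:
    """Binary interaction corrections: k12 on energy, l12 on covolume."""

    k12: float
    l12: float = 0.0

    def __post_init__(self) -> None:
        if not (abs(self.k12) < 1 and abs(self.l12) < 1):
            raise ValidationError("interaction parameters must satisfy |k|, |l| < 1")

    def to_dict(self) -> dict:
        return {"k12": self.k12, "l12": self.l12}


@dataclass(frozen=True)
class EoSState:
    temperature: float
    pressure: float
    composition: tuple[float, ...]
    compressibility: float
    mixture_a: float
    mixture_b: float


def kappa(omega: float) -> float:
    """PR alpha-function slope: 0.37464 + 1.54226 w - 0.26992 w^2."""
    return 0.37464 + 1.54226 * omega - 0.26992 * omega**2


def pure_params(component: EoSComponent, temperature) -> tuple[np.ndarray, float]:
    """PR pure-component energy a(T) (Pa m6/mol2) and covolume b (m3/mol)."""
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= 0):
        raise ValidationError("temperature must be positive")
    tc, pc = component.critical_temperature, component.critical_pressure
    k = kappa(component.acentric_factor)
    alpha = (1.0 + k * (1.0 - np.sqrt(T / tc))) ** 2
    a = 0.45724 * R_GAS**2 * tc**2 / pc * alpha
    b = 0.07780 * R_GAS * tc / pc
    return (a if a.ndim else float(a)), b


def _check_composition(x: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if abs(float(x.sum()) - 1.0) > 1e-9 or np.any(x < 0):
        raise ValidationError(f"composition must be non-negative and sum to 1, got {x}")
    return x


def _pair_matrices(components, temperature, interaction: InteractionParams):
    n = len(components)
    a = np.array([pure_params(c, temperature)[0] for c in components])
    b = np.array([pure_params(c, temperature)[1] for c in components])
    kmat = np.zeros((n, n))
    lmat = np.zeros((n, n))
    if n == 2:
        kmat[0, 1] = kmat[1, 0] = interaction.k12
        lmat[0, 1] = lmat[1, 0] = interaction.l12
    aij = np.sqrt(np.outer(a, a)) * (1.0 - kmat)
    bij = (b[:, None] + b[None, :]) / 2.0 * (1.0 - lmat)
    return aij, bij


def mixture_params(
    components: Sequence[EoSComponent],
    composition: Sequence[float],
    interaction: InteractionParams,
    temperature: float,
) -> tuple[float, float]:
    """Quadratic vdW2 mixing: a_m = sum_ij x_i x_j a_ij (and likewise b_m)."""
    x = _check_composition(composition)
    aij, bij = _pair_matrices(components, temperature, interaction)
    return float(x @ aij @ x), float(x @ bij @ x)


def _cubic_coeffs(A, B):
    c2 = -(1.0 - B)
    c1 = A - 3.0 * B**2 - 2.0 * B
    c0 = -(A * B - B**2 - B**3)
    return c2, c1, c0


def _real_cubic_roots(c2, c1, c0):
    """Real roots of z^3 + c2 z^2 + c1 z + c0, vectorised; NaN-padded (n, 3)."""
    c2, c1, c0 = np.broadcast_arrays(*(np.atleast_1d(np.asarray(v, float))
                                       for v in (c2, c1, c0)))
    p = c1 - c2**2 / 3.0
    q = 2.0 * c2**3 / 27.0 - c2 * c1 / 3.0 + c0
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    roots = np.full(c2.shape + (3,), np.nan)
    one = disc > 0
    if np.any(one):
        s = np.sqrt(disc[one])
        u = np.cbrt(-q[one] / 2.0 + s)
        v = np.cbrt(-q[one] / 2.0 - s)
        roots[one, 0] = u + v - c2[one] / 3.0
    three = ~one
    if np.any(three):
        pm = np.minimum(p[three], -1e-300)
        m = 2.0 * np.sqrt(-pm / 3.0)
        arg = np.clip(3.0 * q[three] / (pm * m), -1.0, 1.0)
        theta = np.arccos(arg) / 3.0
        for j in range(3):
            roots[three, j] = m * np.cos(theta - 2.0 * np.pi * j / 3.0) - c2[three] / 3.0
    return roots


def _residual_gibbs(Z, A, B):
    with np.errstate(invalid="ignore", divide="ignore"):
        return (
            Z - 1.0 - np.log(Z - B)
            - A / (2.0 * _SQRT2 * B)
            * np.log((Z + (1.0 + _SQRT2) * B) / (Z + (1.0 - _SQRT2) * B))
        )


def _select_root(A, B):
    """Fluid-phase compressibility: the real root (v > b) of least Gibbs energy."""
    A = np.atleast_1d(np.asarray(A, float))
    B = np.atleast_1d(np.asarray(B, float))
    roots = _real_cubic_roots(*_cubic_coeffs(A, B))
    valid = np.isfinite(roots) & (roots > B[..., None] * (1.0 + 1e-12))
    g = np.where(valid, _residual_gibbs(roots, A[..., None], B[..., None]), np.inf)
    g = np.where(np.isfinite(g), g, np.inf)
    best = np.argmin(g, axis=-1)
    Z = np.take_along_axis(roots, best[..., None], axis=-1)[..., 0]
    Z = np.where(valid.any(axis=-1), Z, np.nan)
    return Z


def solve_compressibility(temperature, pressure, a_m, b_m) -> np.ndarray:
    """All physically admissible real compressibility roots at (T, P)."""
    if not pressure > 0:
        raise ValidationError("pressure must be positive")
    A = a_m * pressure / (R_GAS * temperature) ** 2
    B = b_m * pressure / (R_GAS * temperature)
    roots = _real_cubic_roots(*_cubic_coeffs(A, B))[0]
    out = np.sort(roots[np.isfinite(roots) & (roots > B)])
    if out.size == 0:
        raise ValidationError(
            f"no compressibility root with v > b at T={temperature}, P={pressure}"
        )
    return out


def _lnphi_binary(T, P, y2, components, interaction):
    """Vectorised PR/vdW2 log fugacity coefficients for a binary mixture.

    Returns (lnphi1, lnphi2, Z) over broadcast arrays of T (K), P (Pa) and
    solute fraction y2.  NaN propagates where no valid root exists.
    """
    T, P, y2 = np.broadcast_arrays(*(np.atleast_1d(np.asarray(v, float))
                                     for v in (T, P, y2)))
    c1, c2 = components
    a1, b1 = pure_params(c1, T)
    a2, b2 = pure_params(c2, T)
    a12 = np.sqrt(a1 * a2) * (1.0 - interaction.k12)
    b12 = (b1 + b2) / 2.0 * (1.0 - interaction.l12)
    x1 = 1.0 - y2
    am = x1**2 * a1 + 2.0 * x1 * y2 * a12 + y2**2 * a2
    bm = x1**2 * b1 + 2.0 * x1 * y2 * b12 + y2**2 * b2
    A = am * P / (R_GAS * T) ** 2
    B = bm * P / (R_GAS * T)
    Z = _select_root(A, B)
    # partial-molar covolume d(n b_m)/dn_i for quadratic b mixing
    bbar1 = 2.0 * (x1 * b1 + y2 * b12) - bm
    bbar2 = 2.0 * (x1 * b12 + y2 * b2) - bm
    asum1 = x1 * a1 + y2 * a12
    asum2 = x1 * a12 + y2 * a2
    with np.errstate(invalid="ignore", divide="ignore"):
        ln_term = np.log((Z + (1.0 + _SQRT2) * B) / (Z + (1.0 - _SQRT2) * B))
        core = A / (2.0 * _SQRT2 * B) * ln_term
        lnz_b = np.log(Z - B)
        lnphi1 = bbar1 / bm * (Z - 1.0) - lnz_b - core * (2.0 * asum1 / am - bbar1 / bm)
        lnphi2 = bbar2 / bm * (Z - 1.0) - lnz_b - core * (2.0 * asum2 / am - bbar2 / bm)
    return lnphi1, lnphi2, Z


def state_at(
    temperature: float,
    pressure: float,
    composition: Sequence[float],
    components: Sequence[EoSComponent],
    interaction: InteractionParams,
) -> EoSState:
    x = _check_composition(composition)
    am, bm = mixture_params(components, x, interaction, temperature)
    roots = solve_compressibility(temperature, pressure, am, bm)
    A = am * pressure / (R_GAS * temperature) ** 2
    B = bm * pressure / (R_GAS * temperature)
    g = _residual_gibbs(roots, A, B)
    Z = float(roots[np.argmin(g)])
    return EoSState(temperature, pressure, tuple(x), Z, am, bm)


def fugacity_coefficient(
    index: int,
    temperature: float,
    pressure: float,
    composition: Sequence[float],
    components: Sequence[EoSComponent] = (CO2_COMPONENT,),
    interaction: InteractionParams = InteractionParams(0.0, 0.0),
) -> float:
    """Fugacity coefficient phi_i of component ``index`` in the mixture.

    For a pure component pass a one-entry composition/component list.
    """
    x = _check_composition(composition)
    if len(x) == 1:
        # pure-component limit: treat as a degenerate binary with itself
        comps = (components[0], components[0])
        lnphi1, _, Z = _lnphi_binary(temperature, pressure, 0.0, comps, interaction)
        val = lnphi1[0]
    elif len(x) == 2:
        lnphi1, lnphi2, Z = _lnphi_binary(
            temperature, pressure, x[1], components, interaction
        )
        val = (lnphi1 if index == 0 else lnphi2)[0]
    else:
        raise ValidationError("only pure and binary mixtures are supported")
    if not np.isfinite(val):
        raise ValidationError(
            f"no valid fluid root at T={temperature}, P={pressure}"
        )
    return float(np.exp(val))


def _residual_helmholtz_over_rt(temperature, volume, moles, components, interaction):
    """A_res(T, V, n)/RT from the total-system PR parameters."""
    n = np.asarray(moles, dtype=float)
    ntot = n.sum()
    aij, bij = _pair_matrices(components, temperature, interaction)
    a_tot = float(n @ aij @ n)  # n^2 a_m
    b_tot = float(n @ bij @ n) / ntot  # n b_m
    rt = R_GAS * temperature
    return (
        -ntot * np.log((volume - b_tot) / volume)
        - a_tot / (2.0 * _SQRT2 * b_tot * rt)
        * np.log((volume + (1.0 + _SQRT2) * b_tot) / (volume + (1.0 - _SQRT2) * b_tot))
    )


def fugacity_coefficient_numerical(
    index: int,
    temperature: float,
    pressure: float,
    composition: Sequence[float],
    components: Sequence[EoSComponent],
    interaction: InteractionParams,
    h: float = 1e-6,
) -> float:
    """phi_i by central-difference differentiation of the residual Helmholtz
    energy at fixed (T, V) -- the textbook integral definition evaluated
    numerically, independent of the closed-form expression."""
    x = _check_composition(composition)
    st = state_at(temperature, pressure, x, components, interaction)
    volume = st.compressibility * R_GAS * temperature / pressure  # per 1 mol total
    n = np.array(x, dtype=float)

    def ares(nvec):
        return _residual_helmholtz_over_rt(
            temperature, volume, nvec, components, interaction
        )

    np_ = n.copy()
    nm = n.copy()
    np_[index] += h
    nm[index] -= h
    dadn = (ares(np_) - ares(nm)) / (2.0 * h)
    return float(np.exp(dadn - np.log(st.compressibility)))


def sublimation_pressure(
    temperature,
    boiling_temperature: float = METHYLDOPA.boiling_temperature,
    entropy_of_boiling: float = _GRAIN_DSB,
) -> float | np.ndarray:
    """Solid sublimation pressure (Pa) from the modified-Grain correlation.

    ln(P/P_atm) = (dS_b/R) [1 - (3 - 2 Tpt)^m / Tpt - 2 m (3 - 2 Tpt)^(m-1)
    ln Tpt], with Tpt = T/T_b and m = 0.4133 - 0.2575 Tpt.  Only the boiling
    temperature is required; the estimate equals P_atm exactly at T = T_b.

    ``entropy_of_boiling`` (J/mol/K) sets the magnitude and temperature slope
    of the estimate; the default 86.9 corresponds to a strongly associating
    solid.  Fishtine-style values K_F (8.75 + R ln T_b) can be passed here,
    or a whole alternative estimator injected through
    ``SolutePhysProps.sublimation_pressure_override``.
    """
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= 0) or np.any(T > boiling_temperature):
        raise ValidationError("require 0 < T <= boiling_temperature")
    tpt = T / boiling_temperature
    m = 0.4133 - 0.2575 * tpt
    bracket = (
        1.0
        - (3.0 - 2.0 * tpt) ** m / tpt
        - 2.0 * m * (3.0 - 2.0 * tpt) ** (m - 1.0) * np.log(tpt)
    )
    out = P_ATM * np.exp(entropy_of_boiling / R_GAS * bracket)
    return out if out.ndim else float(out)


def _sublimation(T, props: SolutePhysProps):
    if props.sublimation_pressure_override is not None:
        f = props.sublimation_pressure_override
        arr = np.asarray(T, dtype=float)
        if arr.ndim:
            return np.array([float(f(t)) for t in arr])
        return float(f(float(arr)))
    return sublimation_pressure(T, props.boiling_temperature)


def solubility_eos_grid(
    temperature,
    pressure_pa,
    props: SolutePhysProps = METHYLDOPA,
    interaction: InteractionParams = InteractionParams(0.0, 0.0),
    *,
    assume_ideal_fugacity: bool = False,
    y0: float = 1e-5,
    rtol: float = 1e-10,
    max_iter: int = 200,
) -> np.ndarray:
    """Vectorised solid-solubility solve over arrays of (T/K, P/Pa).

    Returns NaN at conditions where the fixed point fails (no valid fluid
    root, divergence, or y2 >= 1); the scalar wrapper raises instead.
    """
    T, P = np.broadcast_arrays(np.atleast_1d(np.asarray(temperature, float)),
                               np.atleast_1d(np.asarray(pressure_pa, float)))
    psub = np.atleast_1d(np.asarray(_sublimation(T, props), float))
    if np.any(P <= psub):
        raise ValidationError("system pressure must exceed the sublimation pressure")
    v2s = props.solid_molar_volume * 1e-6  # cm3/mol -> m3/mol
    base = psub / P * np.exp(v2s * (P - psub) / (R_GAS * T))  # phi2_sat = 1
    if assume_ideal_fugacity:
        return base
    components = (CO2_COMPONENT, component_from_props(props))
    y = np.full_like(base, y0)
    converged = np.zeros(y.shape, dtype=bool)
    failed = np.zeros(y.shape, dtype=bool)
    for _ in range(max_iter):
        _, lnphi2, _ = _lnphi_binary(T, P, y, components, interaction)
        with np.errstate(over="ignore", invalid="ignore"):
            y_new = base / np.exp(lnphi2)
        failed |= ~np.isfinite(y_new) | (y_new >= 1.0) | (y_new <= 0.0)
        y_new = np.where(failed, y, y_new)
        delta = np.abs(y_new - y) / np.maximum(y_new, 1e-300)
        y = y_new
        converged = delta < rtol
        if np.all(converged | failed):
            break
    return np.where(converged & ~failed, y, np.nan)


def solubility_eos(
    temperature: float,
    pressure_pa: float,
    props: SolutePhysProps = METHYLDOPA,
    interaction: InteractionParams = InteractionParams(0.0, 0.0),
    **kwargs,
) -> float:
    """Solute mole fraction from the solid-fluid equilibrium condition.

    Solves y2 = (P2sub/P)(phi2_sat/phi2(T,P,y)) exp(v2s (P - P2sub)/RT) by
    fixed-point iteration from y2 = 1e-5 (phi2 depends on y2 through the
    mixture parameters).
    """
    out = solubility_eos_grid(
        temperature, pressure_pa, props, interaction, **kwargs
    )
    val = float(out[0])
    if not np.isfinite(val):
        raise ConvergenceError(
            f"solubility solve failed at T={temperature}, P={pressure_pa} "
            f"with {interaction}"
        )
    return val


def _collection_si(collection: IsothermCollection):
    return collection.temperature, collection.pressure * 1e6, collection.mole_fraction


def fit_interaction_params(
    collection: IsothermCollection,
    props: SolutePhysProps = METHYLDOPA,
    config=None,
    *,
    scope: str = "global",
    bounds: Sequence[tuple[float, float]] = ((-0.9, 0.9), (-0.9, 0.9)),
):
    """Regress (k12, l12) against a binary solubility collection.

    ``scope='global'`` (default) fits one pair to all records and returns
    ``(InteractionParams, FitMetrics)``; ``scope='per-isotherm'`` fits each
    temperature separately and returns a ``{T: (InteractionParams,
    FitMetrics)}`` map.  The objective is the AARD of predicted vs observed
    mole fractions, minimised with the same seeded annealing machinery as the
    density-model fits.
    """
    from .fitting import FitMetrics, OptimizerConfig, aard, aicc, anneal_minimize, r_squared

    cfg = config or OptimizerConfig(n_restarts=4, steps_per_temp=50, n_temps=60)
    if scope == "per-isotherm":
        return {
            t: fit_interaction_params(sub, props, config, scope="global", bounds=bounds)
            for t, sub in collection.isotherms().items()
        }
    if scope != "global":
        raise ConfigError("scope must be 'global' or 'per-isotherm'")

    T, P, y_obs = _collection_si(collection)
    if np.any(collection.cosolvent_fraction > 0):
        raise ValidationError("EoS regression applies to the binary system only")

    def objective(x):
        try:
            inter = InteractionParams(float(x[0]), float(x[1]))
        except ValidationError:
            return 1e12
        y_pred = solubility_eos_grid(T, P, props, inter)
        if not np.all(np.isfinite(y_pred)):
            return 1e12
        return aard(y_obs, y_pred)

    best, best_f, trace = anneal_minimize(objective, list(bounds), cfg, x0=np.zeros(2))
    inter = InteractionParams(float(best[0]), float(best[1]))
    y_pred = solubility_eos_grid(T, P, props, inter)
    sse = float(np.sum((y_pred - y_obs) ** 2))
    metrics = FitMetrics(
        aard_percent=aard(y_obs, y_pred),
        r_squared=r_squared(y_obs, y_pred),
        aicc=aicc(sse, len(y_obs), 2),
        sse=sse,
        n_points=len(y_obs),
        n_params=2,
    )
    return inter, metrics
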