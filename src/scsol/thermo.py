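"""Post-fit thermodynamics and cosolvent analysis.

Covers the van't-Hoff-style enthalpy decomposition (total enthalpy from the
Chrastil 1/T coefficient, vaporization enthalpy from the Bartle 1/T
coefficient, solvation enthalpy as their difference), mole-fraction <->
mass-solubility conversion, cosolvent enhancement factors, and the
crossover-pressure estimate where solubility isotherms intersect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._constants import M_CO2, METHYLDOPA_MW, R_GAS
from .dataset import IsothermCollection
from .errors import PairingError, ValidationError

__all__ = [
    "EnthalpyReport",
    "total_enthalpy_from_chrastil",
    "vaporization_enthalpy_from_bartle",
    "solvation_enthalpy",
    "enthalpy_report",
    "mass_solubility",
    "mole_fraction_from_mass_solubility",
    "enhancement_factors",
    "CrossoverReport",
    "crossover_pressure",
]


@dataclass(frozen=True)
class EnthalpyReport:
    """Enthalpy decomposition in kJ/mol: solvation = total - vaporization."""

    total_kj_mol: float
    vaporization_kj_mol: float

    @property
    def solvation_kj_mol(self) -> float:
        return self.total_kj_mol - self.vaporization_kj_mol

    def to_dict(self) -> dict:
        return {
            "total_kj_mol": self.total_kj_mol,
            "vaporization_kj_mol": self.vaporization_kj_mol,
            "solvation_kj_mol": self.solvation_kj_mol,
        }


def _inv_T_coefficient(fitted, expected_id: str) -> float:
    model_id = fitted.spec.model_id
    if model_id != expected_id:
        raise TypeError(f"expected a fitted {expected_id} model, got {model_id!r}")
    return float(np.asarray(fitted.params)[1])  # a1 multiplies 1/T in both forms


def total_enthalpy_from_chrastil(fitted) -> float:
    """Total enthalpy (kJ/mol) from the Chrastil 1/T coefficient: -a1*R."""
    return -_inv_T_coefficient(fitted, "chrastil") * R_GAS / 1000.0


def vaporization_enthalpy_from_bartle(fitted) -> float:
    """Vaporization enthalpy (kJ/mol) from the Bartle 1/T coefficient: -a1*R."""
    return -_inv_T_coefficient(fitted, "bartle") * R_GAS / 1000.0


def solvation_enthalpy(total_kj_mol: float, vaporization_kj_mol: float) -> float:
    """Solvation enthalpy as the exact difference total - vaporization."""
    return total_kj_mol - vaporization_kj_mol


def enthalpy_report(chrastil_fit, bartle_fit) -> EnthalpyReport:
    return EnthalpyReport(
        total_kj_mol=total_enthalpy_from_chrastil(chrastil_fit),
        vaporization_kj_mol=vaporization_enthalpy_from_bartle(bartle_fit),
    )


def mass_solubility(
    mole_fraction,
    co2_density,
    solute_molar_mass: float = METHYLDOPA_MW,
    co2_molar_mass: float = M_CO2,
):
    """Mass solubility S in g/L from the mole fraction and CO2 density (kg/m3).

    S = rho * M_solute * y / (M_CO2 * (1 - y)).
    """
    y = np.asarray(mole_fraction, dtype=float)
    if np.any(y < 0) or np.any(y >= 1):
        raise ValidationError("mole fraction must lie in [0, 1)")
    out = np.asarray(co2_density, dtype=float) * solute_molar_mass * y / (
        co2_molar_mass * (1.0 - y)
    )
    return out if out.ndim else float(out)


def mole_fraction_from_mass_solubility(
    solubility_g_l,
    co2_density,
    solute_molar_mass: float = METHYLDOPA_MW,
    co2_molar_mass: float = M_CO2,
):
    """Inverse of :func:`mass_solubility`."""
    s = np.asarray(solubility_g_l, dtype=float)
    if np.any(s < 0):
        raise ValidationError("mass solubility must be non-negative")
    ratio = s * co2_molar_mass / (np.asarray(co2_density, float) * solute_molar_mass)
    out = ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def enhancement_factors(
    binary: IsothermCollection, ternary: IsothermCollection
) -> pd.DataFrame:
    """Cosolvent enhancement e = y2'/y2 at matched (T, P) conditions.

    The ratio convention matches the tabulated data of the packaged study;
    some sources print the same quantity scaled by 100.
    """
    lookup = {(r.temperature, r.pressure): r.mole_fraction for r in binary}
    missing = [
        (r.temperature, r.pressure)
        for r in ternary
        if (r.temperature, r.pressure) not in lookup
    ]
    if missing:
        raise PairingError(
            f"ternary conditions with no binary match on (T, P): {missing}"
        )
    rows = [
        {
            "temperature": r.temperature,
            "pressure": r.pressure,
            "cosolvent_fraction": r.cosolvent_fraction,
            "enhancement": r.mole_fraction / lookup[(r.temperature, r.pressure)],
        }
        for r in ternary
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CrossoverReport:
    """Per-isotherm-pair crossover pressures and their median."""

    pairs: tuple[dict, ...]
    aggregate_mpa: float | None

    def to_dict(self) -> dict:
        return {"pairs": list(self.pairs), "aggregate_mpa": self.aggregate_mpa}


def _pair_crossings(p: np.ndarray, d: np.ndarray) -> list[tuple[float, tuple]]:
    """Zero crossings of d(P) under piecewise-linear interpolation."""
    out = []
    for k in range(len(p) - 1):
        d0, d1 = d[k], d[k + 1]
        if d0 == 0.0:
            out.append((float(p[k]), (float(p[k]), float(p[k]))))
        elif d0 * d1 < 0:
            frac = d0 / (d0 - d1)
            out.append(
                (float(p[k] + frac * (p[k + 1] - p[k])), (float(p[k]), float(p[k + 1])))
            )
    if len(d) and d[-1] == 0.0:
        out.append((float(p[-1]), (float(p[-1]), float(p[-1]))))
    return out


def crossover_pressure(collection: IsothermCollection) -> CrossoverReport:
    """Crossover pressures where solubility isotherms intersect.

    For every pair of isotherms the intersection of the piecewise-linear
    ln(y) vs P interpolants on their common pressure grid is located; a pair
    with several crossings contributes its median.  The aggregate estimate is
    the median over pairs; pairs that never cross are reported without a
    pressure and do not enter the aggregate.
    """
    iso = collection.isotherms()
    temps = sorted(iso)
    if len(temps) < 2:
        raise ValidationError("crossover detection needs >= 2 isotherms")
    pairs: list[dict] = []
    estimates: list[float] = []
    for i, t1 in enumerate(temps):
        for t2 in temps[i + 1:]:
            a, b = iso[t1], iso[t2]
            pa = {r.pressure: r.mole_fraction for r in a}
            pb = {r.pressure: r.mole_fraction for r in b}
            if len(pa) != len(a) or len(pb) != len(b):
                raise ValidationError(
                    "duplicate pressures within an isotherm; subset the "
                    "collection to one cosolvent level first"
                )
            common = np.array(sorted(set(pa) & set(pb)))
            if len(common) < 2:
                continue
            d = np.array([np.log(pa[p]) - np.log(pb[p]) for p in common])
            crossings = _pair_crossings(common, d)
            entry = {"t_low": t1, "t_high": t2}
            if crossings:
                ps = sorted(c[0] for c in crossings)
                mid = ps[(len(ps) - 1) // 2]
                bracket = next(c[1] for c in crossings if c[0] == mid)
                entry.update({"pressure_mpa": mid, "bracket_mpa": list(bracket)})
                estimates.append(mid)
            else:
                entry.update({"pressure_mpa": None, "bracket_mpa": None})
            pairs.append(entry)
    aggregate = float(np.median(estimates)) if estimates else None
    return CrossoverReport(tuple(pairs), aggregate)
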