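"""Solubility tables: records, collections, packaged fixtures and density lookup.

The packaged dataset holds isothermal solubility measurements of methyldopa in
supercritical CO2, with and without ethanol cosolvent, on a 4-temperature
(308-338 K) by 7-pressure (12-30 MPa) grid.  Mole fractions are stored as plain
dimensionless values (e.g. 2.38e-5), never on the x1e4 scale used in printed
tables; loaders accept a scale hint for tables stored that way.

Ternary records carry the pure-CO2 density at the same (T, P) as the binary
table: all density models use the solvent density as the correlating variable,
and the qualitative density increase from 1-3 mol% ethanol is not resolved by
the source data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from ._constants import (
    M_CO2,
    METHYLDOPA_MW,
    METHYLDOPA_OMEGA,
    METHYLDOPA_PC,
    METHYLDOPA_TB,
    METHYLDOPA_TC,
    METHYLDOPA_VS,
)
from .errors import GridLookupError, SchemaError, ValidationError

__all__ = [
    "SolubilityRecord",
    "IsothermCollection",
    "SolutePhysProps",
    "METHYLDOPA",
    "CSV_COLUMNS",
    "BUILTIN_SYSTEMS",
    "load_solubility_table",
    "save_solubility_table",
    "builtin_dataset",
    "CO2DensityTable",
    "density_lookup",
    "mole_fraction_from_masses",
]

CSV_COLUMNS = ("system", "T_K", "P_MPa", "rho_kg_m3", "y2", "y3", "sd")

#: labels of the shipped fixture systems
BUILTIN_SYSTEMS = ("binary", "ethanol-1%", "ethanol-3%", "ternary")

_FIXTURE_FILES = {
    "binary": "binary.csv",
    "ethanol-1%": "ethanol-1.csv",
    "ethanol-3%": "ethanol-3.csv",
}


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium observation.

    Attributes
    ----------
    temperature : float
        Kelvin.
    pressure : float
        MPa.
    co2_density : float
        Pure-CO2 density at (T, P), kg/m3.
    mole_fraction : float
        Solute mole fraction (y2 binary, y2' ternary), dimensionless.
    cosolvent_fraction : float
        Cosolvent mole fraction y3 (0 for binary systems).
    sd : float or None
        Replicate standard deviation of the mole fraction, if measured.
    """

    temperature: float
    pressure: float
    co2_density: float
    mole_fraction: float
    cosolvent_fraction: float = 0.0
    sd: float | None = None

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.pressure > 0:
            raise ValidationError(f"pressure must be > 0 MPa, got {self.pressure}")
        if not self.co2_density > 0:
            raise ValidationError(f"co2_density must be > 0, got {self.co2_density}")
        if not 0.0 < self.mole_fraction < 1.0:
            raise ValidationError(
                f"mole_fraction must lie in (0, 1), got {self.mole_fraction}"
            )
        if not 0.0 <= self.cosolvent_fraction < 1.0:
            raise ValidationError(
                f"cosolvent_fraction must lie in [0, 1), got {self.cosolvent_fraction}"
            )


@dataclass(frozen=True)
class IsothermCollection:
    """An ordered set of solubility records, groupable into isotherms.

    Records are sorted by (temperature, pressure, cosolvent_fraction) on
    construction; duplicate conditions are rejected so that each isotherm has
    strictly increasing pressures.
    """

    records: tuple[SolubilityRecord, ...]
    system_label: str = ""

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValidationError("collection must contain at least one record")
        ordered = tuple(
            sorted(
                self.records,
                key=lambda r: (r.temperature, r.cosolvent_fraction, r.pressure),
            )
        )
        keys = [(r.temperature, r.cosolvent_fraction, r.pressure) for r in ordered]
        for a, b in zip(keys, keys[1:]):
            if a == b:
                raise ValidationError(f"duplicate condition {a} in collection")
        object.__setattr__(self, "records", ordered)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SolubilityRecord]:
        return iter(self.records)

    # -- array views -------------------------------------------------------
    @property
    def temperature(self) -> np.ndarray:
        return np.array([r.temperature for r in self.records], dtype=float)

    @property
    def pressure(self) -> np.ndarray:
        return np.array([r.pressure for r in self.records], dtype=float)

    @property
    def co2_density(self) -> np.ndarray:
        return np.array([r.co2_density for r in self.records], dtype=float)

    @property
    def mole_fraction(self) -> np.ndarray:
        return np.array([r.mole_fraction for r in self.records], dtype=float)

    @property
    def cosolvent_fraction(self) -> np.ndarray:
        return np.array([r.cosolvent_fraction for r in self.records], dtype=float)

    @property
    def sd(self) -> np.ndarray:
        return np.array(
            [np.nan if r.sd is None else r.sd for r in self.records], dtype=float
        )

    def isotherms(self) -> dict[float, "IsothermCollection"]:
        """Group records by temperature, preserving the sorted order."""
        out: dict[float, IsothermCollection] = {}
        for t in sorted({r.temperature for r in self.records}):
            recs = tuple(r for r in self.records if r.temperature == t)
            out[t] = IsothermCollection(recs, system_label=self.system_label)
        return out

    def subset(self, predicate: Callable[[SolubilityRecord], bool]) -> "IsothermCollection":
        recs = tuple(r for r in self.records if predicate(r))
        return IsothermCollection(recs, system_label=self.system_label)

    def merged(self, other: "IsothermCollection", label: str) -> "IsothermCollection":
        return IsothermCollection(self.records + other.records, system_label=label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "system": self.system_label,
                "T_K": self.temperature,
                "P_MPa": self.pressure,
                "rho_kg_m3": self.co2_density,
                "y2": self.mole_fraction,
                "y3": self.cosolvent_fraction,
                "sd": self.sd,
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "system": self.system_label,
            "records": [
                {
                    "T_K": r.temperature,
                    "P_MPa": r.pressure,
                    "rho_kg_m3": r.co2_density,
                    "y2": r.mole_fraction,
                    "y3": r.cosolvent_fraction,
                    "sd": r.sd,
                }
                for r in self.records
            ],
        }


@dataclass(frozen=True)
class SolutePhysProps:
    """Physical property set of the solid solute.

    ``sublimation_pressure_override``, if given, is called as ``f(T) -> Pa``
    in place of the built-in boiling-point estimate (see :mod:`scsol.pr_eos`).
    """

    molar_mass: float  # g/mol
    boiling_temperature: float  # K
    critical_temperature: float  # K
    critical_pressure: float  # Pa
    acentric_factor: float
    solid_molar_volume: float  # cm3/mol
    sublimation_pressure_override: Callable[[float], float] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        for name in (
            "molar_mass",
            "boiling_temperature",
            "critical_temperature",
            "critical_pressure",
            "acentric_factor",
            "solid_molar_volume",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not self.critical_temperature > self.boiling_temperature:
            raise ValidationError("critical_temperature must exceed boiling_temperature")


#: default solute property set (methyldopa)
METHYLDOPA = SolutePhysProps(
    molar_mass=METHYLDOPA_MW,
    boiling_temperature=METHYLDOPA_TB,
    critical_temperature=METHYLDOPA_TC,
    critical_pressure=METHYLDOPA_PC,
    acentric_factor=METHYLDOPA_OMEGA,
    solid_molar_volume=METHYLDOPA_VS,
)

_DEFAULT_SCHEMA = {
    "temperature": "T_K",
    "pressure": "P_MPa",
    "co2_density": "rho_kg_m3",
    "mole_fraction": "y2",
    "cosolvent_fraction": "y3",
    "sd": "sd",
}


def load_solubility_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    mole_fraction_scale: float = 1.0,
    system_label: str | None = None,
) -> IsothermCollection:
    """Read a solubility CSV into an :class:`IsothermCollection`.

    Parameters
    ----------
    path
        CSV file with a header row (comma separated, '.' decimal mark).
    schema
        Optional map from field names (``temperature``, ``pressure``,
        ``co2_density``, ``mole_fraction``, ``cosolvent_fraction``, ``sd``)
        to the column names used in the file.
    mole_fraction_scale
        Multiplier applied to the mole-fraction (and sd) columns; pass 1e-4
        for tables stored on the printed x1e4 scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path} is empty") from exc
    if frame.empty:
        raise ValidationError(f"{path} contains no data rows")

    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    for fieldname in ("temperature", "pressure", "co2_density", "mole_fraction"):
        if colmap[fieldname] not in frame.columns:
            raise SchemaError(
                f"required column {colmap[fieldname]!r} (field {fieldname!r}) "
                f"missing from {path}"
            )
    has_y3 = colmap["cosolvent_fraction"] in frame.columns
    has_sd = colmap["sd"] in frame.columns

    records: list[SolubilityRecord] = []
    rejected: list[int] = []
    for idx, row in frame.iterrows():
        vals = {
            "temperature": float(row[colmap["temperature"]]),
            "pressure": float(row[colmap["pressure"]]),
            "co2_density": float(row[colmap["co2_density"]]),
            "mole_fraction": float(row[colmap["mole_fraction"]]) * mole_fraction_scale,
            "cosolvent_fraction": float(row[colmap["cosolvent_fraction"]]) if has_y3 else 0.0,
        }
        sd = float(row[colmap["sd"]]) * mole_fraction_scale if has_sd else np.nan
        if not all(np.isfinite(v) for v in vals.values()):
            rejected.append(int(idx))
            continue
        for key in ("temperature", "pressure", "co2_density"):
            if vals[key] <= 0:
                raise ValidationError(f"row {idx}: non-positive {key} ({vals[key]})")
        records.append(
            SolubilityRecord(sd=None if not np.isfinite(sd) else sd, **vals)
        )
    if rejected:
        warnings.warn(
            f"{path}: rejected rows with non-finite fields: {rejected}",
            stacklevel=2,
        )
    if not records:
        raise ValidationError(f"{path}: no valid rows")
    if system_label is None:
        system_label = (
            str(frame["system"].iloc[0]) if "system" in frame.columns else path.stem
        )
    return IsothermCollection(tuple(records), system_label=system_label)


def save_solubility_table(collection: IsothermCollection, path: str | Path) -> None:
    """Write a collection to CSV at full float precision (lossless round trip)."""
    frame = collection.to_frame()
    frame.to_csv(path, index=False, float_format="%.17g")


def builtin_dataset(system_label: str) -> IsothermCollection:
    """Return one of the packaged fixture systems.

    Labels: ``"binary"`` (28 records), ``"ethanol-1%"`` / ``"ethanol-3%"``
    (28 records each at y3 = 0.01 / 0.03) and ``"ternary"`` (the two ethanol
    levels pooled, 56 records).
    """
    if system_label == "ternary":
        return builtin_dataset("ethanol-1%").merged(
            builtin_dataset("ethanol-3%"), label="ternary"
        )
    if system_label not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown system {system_label!r}; valid labels: {list(BUILTIN_SYSTEMS)}"
        )
    ref = resources.files("scsol.data") / _FIXTURE_FILES[system_label]
    with resources.as_file(ref) as fp:
        return load_solubility_table(fp, system_label=system_label)


class CO2DensityTable:
    """Tabulated pure-CO2 density on a rectangular (T, P) grid.

    The packaged table is the NIST density at the experimental grid points.
    Off-grid queries raise unless bilinear interpolation is enabled.
    """

    def __init__(self, table: Mapping[tuple[float, float], float]) -> None:
        if not table:
            raise ValidationError("density table is empty")
        self._table = {(float(t), float(p)): float(r) for (t, p), r in table.items()}
        self.temperatures = np.array(sorted({t for t, _ in self._table}))
        self.pressures = np.array(sorted({p for _, p in self._table}))

    @classmethod
    def from_collection(cls, collection: IsothermCollection) -> "CO2DensityTable":
        return cls(
            {
                (r.temperature, r.pressure): r.co2_density
                for r in collection.records
            }
        )

    @classmethod
    def builtin(cls) -> "CO2DensityTable":
        return cls.from_collection(builtin_dataset("binary"))

    def lookup(self, temperature: float, pressure: float, *, interpolate: bool = False) -> float:
        key = (float(temperature), float(pressure))
        if key in self._table:
            return self._table[key]
        if not interpolate:
            t_near = self.temperatures[np.argmin(np.abs(self.temperatures - key[0]))]
            p_near = self.pressures[np.argmin(np.abs(self.pressures - key[1]))]
            raise GridLookupError(
                f"(T={temperature}, P={pressure}) is off the density grid; "
                f"nearest grid point is (T={t_near}, P={p_near}); "
                "pass interpolate=True for bilinear interpolation"
            )
        return self._interpolate(*key)

    def _interpolate(self, t: float, p: float) -> float:
        ts, ps = self.temperatures, self.pressures
        if not (ts[0] <= t <= ts[-1] and ps[0] <= p <= ps[-1]):
            raise GridLookupError(
                f"(T={t}, P={p}) outside the grid hull "
                f"[{ts[0]}, {ts[-1]}] K x [{ps[0]}, {ps[-1]}] MPa"
            )
        it = int(np.clip(np.searchsorted(ts, t) - 1, 0, len(ts) - 2))
        ip = int(np.clip(np.searchsorted(ps, p) - 1, 0, len(ps) - 2))
        t0, t1 = ts[it], ts[it + 1]
        p0, p1 = ps[ip], ps[ip + 1]
        wt = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
        wp = 0.0 if p1 == p0 else (p - p0) / (p1 - p0)
        corners = [
            self._table[(t0, p0)],
            self._table[(t0, p1)],
            self._table[(t1, p0)],
            self._table[(t1, p1)],
        ]
        return (
            corners[0] * (1 - wt) * (1 - wp)
            + corners[1] * (1 - wt) * wp
            + corners[2] * wt * (1 - wp)
            + corners[3] * wt * wp
        )


_BUILTIN_DENSITY: CO2DensityTable | None = None


def density_lookup(
    temperature: float,
    pressure: float,
    *,
    interpolate: bool = False,
    table: CO2DensityTable | None = None,
) -> float:
    """Pure-CO2 density (kg/m3) at (T/K, P/MPa) from the packaged NIST table."""
    global _BUILTIN_DENSITY
    if table is None:
        if _BUILTIN_DENSITY is None:
            _BUILTIN_DENSITY = CO2DensityTable.builtin()
        table = _BUILTIN_DENSITY
    return table.lookup(temperature, pressure, interpolate=interpolate)


def mole_fraction_from_masses(
    initial_mass: float,
    final_mass: float,
    moles_co2: float,
    molar_mass: float = METHYLDOPA_MW,
) -> float:
    """Solute mole fraction from the gravimetric mass balance.

    The dissolved mass is the drop from the initial to the final tablet mass;
    dividing by the solute molar mass gives moles of drug, and the mole
    fraction follows from the known moles of CO2 in the cell.
    """
    if final_mass < 0 or initial_mass < 0:
        raise ValidationError("masses must be non-negative")
    if final_mass > initial_mass:
        raise ValidationError(
            "final mass exceeds initial mass: dissolved mass cannot be negative"
        )
    if not moles_co2 > 0:
        raise ValidationError("moles_co2 must be positive")
    moles_drug = (initial_mass - final_mass) / molar_mass
    return moles_drug / (moles_drug + moles_co2)
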