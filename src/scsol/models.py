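"""Semi-empirical density-based solubility models.

Ten correlations are provided: four for binary (solute + scCO2) systems --
Chrastil, Bartle, Kumar-Johnston (K-J) and Mendez-Santiago-Teja (MST) -- and
six for ternary systems with a cosolvent -- the four-parameter MST extension,
Sodeifian-Sajadian, Gonzalez, Soltani-Mazloumi, Jouyban and Garlapati-Madras.

Every model maps conditions (T, P, rho1, y3) and a parameter vector a0..ak to
a predicted response: the solute mole fraction, except Chrastil which
correlates the mass solubility S in g/L.  All ten forms are linear in their
parameters after a fixed transform of the response, which this module exposes
for ordinary-least-squares starting values and for the published
self-consistency (linearised) plots.

Unit conventions inside the formulas (parameters are convention-dependent):
T in K, rho1 in kg/m3, P in MPa -- except Bartle and both MST forms, which use
P in bar with P_ref = 1 bar.  Bartle uses rho_ref = 700 kg/m3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._constants import MPA_TO_BAR
from .dataset import IsothermCollection
from .errors import ValidationError

__all__ = [
    "ModelSpec",
    "Conditions",
    "DensityModel",
    "MODEL_REGISTRY",
    "BINARY_MODELS",
    "TERNARY_MODELS",
    "get_model",
    "evaluate",
    "linearized_coordinates",
    "self_consistency_r2",
]

P_REF_BAR = 1.0
RHO_REF = 700.0  # kg/m3, Bartle reference density


@dataclass(frozen=True)
class Conditions:
    """State variables entering the density models."""

    temperature: float
    pressure: float
    co2_density: float
    cosolvent_fraction: float = 0.0


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    n_params: int
    requires_cosolvent: bool
    response: str  # "mole_fraction" or "mass_solubility"
    constants: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "n_params": self.n_params,
            "requires_cosolvent": self.requires_cosolvent,
            "response": self.response,
            "constants": dict(self.constants),
        }


class DensityModel:
    """A solubility correlation, linear in its parameters after transform.

    ``design`` builds the regressor matrix X such that, for data exactly on
    the model, ``to_linear(response) = X @ params``.
    """

    def __init__(
        self,
        spec: ModelSpec,
        design: Callable[..., np.ndarray],
        to_linear: Callable[..., np.ndarray],
        from_linear: Callable[..., np.ndarray],
        abscissa_column: int,
        param_names: tuple[str, ...],
    ) -> None:
        self.spec = spec
        self._design = design
        self._to_linear = to_linear
        self._from_linear = from_linear
        self.abscissa_column = abscissa_column
        self.param_names = param_names

    @property
    def model_id(self) -> str:
        return self.spec.model_id

    def _check(self, params: Sequence[float], y3: np.ndarray) -> np.ndarray:
        params = np.asarray(params, dtype=float)
        if params.shape != (self.spec.n_params,):
            raise ValidationError(
                f"{self.model_id} expects {self.spec.n_params} parameters, "
                f"got shape {params.shape}"
            )
        if self.spec.requires_cosolvent and np.any(np.asarray(y3) <= 0):
            raise ValidationError(
                f"{self.model_id} is a ternary model and is undefined at "
                "cosolvent_fraction <= 0"
            )
        return params

    def design(self, T, P, rho, y3) -> np.ndarray:
        T, P, rho, y3 = np.broadcast_arrays(
            *(np.atleast_1d(np.asarray(v, dtype=float)) for v in (T, P, rho, y3))
        )
        return self._design(T, P, rho, y3)

    def predict(self, params: Sequence[float], T, P, rho, y3=0.0) -> np.ndarray:
        """Predicted response (mole fraction, or g/L for Chrastil)."""
        params = self._check(params, np.asarray(y3))
        X = self.design(T, P, rho, y3)
        g = X @ params
        Tb = np.broadcast_to(np.atleast_1d(np.asarray(T, float)), g.shape)
        Pb = np.broadcast_to(np.atleast_1d(np.asarray(P, float)), g.shape)
        return self._from_linear(g, Tb, Pb)

    def to_linear(self, response, T, P) -> np.ndarray:
        """Transform observed responses to the linear-model scale."""
        response = np.asarray(response, dtype=float)
        if np.any(response <= 0):
            raise ValidationError("responses must be strictly positive")
        return self._to_linear(response, np.asarray(T, float), np.asarray(P, float))

    def evaluate(self, params: Sequence[float], conditions: Conditions) -> float:
        c = conditions
        out = self.predict(
            params, c.temperature, c.pressure, c.co2_density, c.cosolvent_fraction
        )
        return float(np.asarray(out).reshape(-1)[0])


def _ln(x):
    return np.log(x)


def _exp_from_linear(g, T, P):
    return np.exp(g)


# --- binary forms ---------------------------------------------------------

def _chrastil_design(T, P, rho, y3):
    return np.column_stack([_ln(rho), 1.0 / T, np.ones_like(T)])


def _kj_design(T, P, rho, y3):
    return np.column_stack([np.ones_like(T), rho, 1.0 / T])


def _bartle_design(T, P, rho, y3):
    return np.column_stack([np.ones_like(T), 1.0 / T, rho - RHO_REF])


def _bartle_to_linear(y, T, P):
    return _ln(y * P * MPA_TO_BAR / P_REF_BAR)


def _bartle_from_linear(g, T, P):
    return np.exp(g) * P_REF_BAR / (P * MPA_TO_BAR)


def _mst_to_linear(y, T, P):
    return T * _ln(y * P * MPA_TO_BAR / P_REF_BAR)


def _mst_from_linear(g, T, P):
    return np.exp(g / T) * P_REF_BAR / (P * MPA_TO_BAR)


def _mst_binary_design(T, P, rho, y3):
    return np.column_stack([np.ones_like(T), rho, T])


# --- ternary forms --------------------------------------------------------

def _mst_ternary_design(T, P, rho, y3):
    return np.column_stack([np.ones_like(T), rho, T, y3])


def _sodeifian_design(T, P, rho, y3):
    return np.column_stack([_ln(rho), rho / T * _ln(rho), rho, _ln(y3 * P)])


def _gonzalez_design(T, P, rho, y3):
    return np.column_stack([_ln(rho), _ln(y3), 1.0 / T, np.ones_like(T)])


def _soltani_design(T, P, rho, y3):
    # the published form carries an explicit minus sign on the ln P term
    return np.column_stack(
        [np.ones_like(T), 1.0 / T, rho / T, -_ln(P), _ln(y3 * rho * T)]
    )


def _jouyban_design(T, P, rho, y3):
    return np.column_stack(
        [np.ones_like(T), y3, rho, P**2, P * T, T / P, _ln(rho)]
    )


def _madras_design(T, P, rho, y3):
    return np.column_stack(
        [
            np.ones_like(T),
            _ln(rho),
            rho,
            1.0 / T,
            _ln(T),
            _ln(y3),
            _ln(y3 * rho * T),
        ]
    )


def _make(model_id, n_params, requires_cosolvent, response, design,
          to_linear, from_linear, abscissa_column, param_names, constants=None):
    spec = ModelSpec(model_id, n_params, requires_cosolvent, response,
                     constants or {})
    return DensityModel(spec, design, to_linear, from_linear,
                        abscissa_column, param_names)


MODEL_REGISTRY: dict[str, DensityModel] = {
    m.model_id: m
    for m in [
        _make(
            "chrastil", 3, False, "mass_solubility",
            _chrastil_design, lambda s, T, P: _ln(s), _exp_from_linear,
            abscissa_column=0, param_names=("a0", "a1", "a2"),
        ),
        _make(
            "bartle", 3, False, "mole_fraction",
            _bartle_design, _bartle_to_linear, _bartle_from_linear,
            abscissa_column=2, param_names=("a0", "a1", "a2"),
            constants={"P_ref_bar": P_REF_BAR, "rho_ref": RHO_REF},
        ),
        _make(
            "kumar_johnston", 3, False, "mole_fraction",
            _kj_design, lambda y, T, P: _ln(y), _exp_from_linear,
            abscissa_column=1, param_names=("a0", "a1", "a2"),
        ),
        _make(
            "mst_binary", 3, False, "mole_fraction",
            _mst_binary_design, _mst_to_linear, _mst_from_linear,
            abscissa_column=1, param_names=("a0", "a1", "a2"),
            constants={"P_ref_bar": P_REF_BAR},
        ),
        _make(
            "mst_ternary", 4, True, "mole_fraction",
            _mst_ternary_design, _mst_to_linear, _mst_from_linear,
            abscissa_column=1, param_names=("a0", "a1", "a2", "a3"),
            constants={"P_ref_bar": P_REF_BAR},
        ),
        _make(
            "sodeifian_sajadian", 4, True, "mole_fraction",
            _sodeifian_design, lambda y, T, P: _ln(y), _exp_from_linear,
            abscissa_column=2, param_names=("a0", "a1", "a2", "a3"),
        ),
        _make(
            "gonzalez", 4, True, "mole_fraction",
            _gonzalez_design, lambda y, T, P: _ln(y), _exp_from_linear,
            abscissa_column=0, param_names=("a0", "a1", "a2", "a3"),
        ),
        _make(
            "soltani_mazloumi", 5, True, "mole_fraction",
            _soltani_design, lambda y, T, P: _ln(y), _exp_from_linear,
            abscissa_column=2, param_names=("a0", "a1", "a2", "a3", "a4"),
        ),
        _make(
            "jouyban", 7, True, "mole_fraction",
            _jouyban_design, lambda y, T, P: _ln(y), _exp_from_linear,
            abscissa_column=2,
            param_names=("a0", "a1", "a2", "a3", "a4", "a5", "a6"),
        ),
        _make(
            "garlapati_madras", 7, True, "mole_fraction",
            _madras_design, lambda y, T, P: _ln(y), _exp_from_linear,
            abscissa_column=1,
            param_names=("a0", "a1", "a2", "a3", "a4", "a5", "a6"),
        ),
    ]
}

BINARY_MODELS = tuple(
    m for m, v in MODEL_REGISTRY.items() if not v.spec.requires_cosolvent
)
TERNARY_MODELS = tuple(
    m for m, v in MODEL_REGISTRY.items() if v.spec.requires_cosolvent
)


def get_model(model_id: str) -> DensityModel:
    try:
        return MODEL_REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; valid ids: {sorted(MODEL_REGISTRY)}"
        ) from None


def evaluate(model_id: str, params: Sequence[float], conditions: Conditions) -> float:
    """Predicted response of ``model_id`` at one condition."""
    return get_model(model_id).evaluate(params, conditions)


def _collection_response(model: DensityModel, collection: IsothermCollection):
    # Chrastil correlates the mass solubility; everything else the mole fraction
    from .thermo import mass_solubility

    y = collection.mole_fraction
    if model.spec.response == "mass_solubility":
        return mass_solubility(y, collection.co2_density)
    return y


def linearized_coordinates(
    model_id: str, params: Sequence[float], collection: IsothermCollection
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of the model's self-consistency plot.

    Returns (x, y) such that data generated exactly by the model at ``params``
    fall on a straight line: the transformed response minus every model term
    except the abscissa term, plotted against the abscissa regressor (a
    density-linear or log-density axis for all ten models).
    """
    if len(collection) < 2:
        raise ValidationError("self-consistency regression needs >= 2 records")
    model = get_model(model_id)
    params = model._check(params, collection.cosolvent_fraction)
    T, P = collection.temperature, collection.pressure
    X = model.design(T, P, collection.co2_density, collection.cosolvent_fraction)
    g = model.to_linear(_collection_response(model, collection), T, P)
    j = model.abscissa_column
    others = [k for k in range(X.shape[1]) if k != j]
    y = g - X[:, others] @ params[others]
    return X[:, j], y


def self_consistency_r2(
    model_id: str, params: Sequence[float], collection: IsothermCollection
) -> float:
    """R-squared of the straight-line regression on the linearised plot."""
    x, y = linearized_coordinates(model_id, params, collection)
    if np.ptp(x) == 0:
        raise ValidationError("degenerate abscissa: all x values identical")
    coeffs = np.polyfit(x, y, 1)
    resid = y - np.polyval(coeffs, x)
    sstot = np.sum((y - y.mean()) ** 2)
    if sstot == 0:
        return 1.0
    return float(1.0 - np.sum(resid**2) / sstot)
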