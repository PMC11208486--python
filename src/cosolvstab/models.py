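"""Model equations for co-solvent induced unfolding and activity.

Two empirical models are evaluated here:

* an extended two-state unfolding model that describes a spectroscopic
  signal (e.g. the nanoDSF F350/330 ratio) as a population-weighted mix of
  a folded and an unfolded linear baseline, with the unfolded fraction
  following a logistic law in the co-solvent concentration, and
* an activity-solvent model that combines a Gaussian "boost" term (raised
  activity at low co-solvent concentrations) with a decaying logistic term
  (loss of activity as the enzyme unfolds).

All concentrations are in % (v/v); ``m_folding`` is in J mol^-1 per % (v/v)
so that ``m_folding / (R * T) * c`` is dimensionless. Public interfaces take
temperatures in degrees Celsius and convert to Kelvin internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "R_GAS",
    "UnfoldingModelParams",
    "ActivityModelParams",
    "eval_unfolding_signal",
    "eval_fraction_unfolded",
    "eval_activity",
    "free_energy_of_folding",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

#: Universal gas constant in J mol^-1 K^-1.
R_GAS = 8.314

ABS_ZERO_C = -273.15


def celsius_to_kelvin(t_celsius: float) -> float:
    return float(t_celsius) - ABS_ZERO_C


def kelvin_to_celsius(t_kelvin: float) -> float:
    return float(t_kelvin) + ABS_ZERO_C


class ParameterError(ValueError):
    """Raised when a model parameter violates its bounds or is non-finite."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")
    return value


def _stable_logistic(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic e^x / (1 + e^x).

    Evaluates through the branch that never exponentiates a positive
    argument, so it is finite for |x| up to (and well beyond) 1e4.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class UnfoldingModelParams:
    """Parameters of the extended two-state unfolding model.

    Attributes
    ----------
    alpha_f, beta_f:
        Intercept and slope of the folded-state baseline (signal units,
        signal units per % (v/v)).
    alpha_u, beta_u:
        Intercept and slope of the unfolded-state baseline.
    m_folding:
        Proportionality constant between co-solvent amount and the free
        energy of folding, J mol^-1 per % (v/v).
    c_u50:
        Co-solvent concentration of half unfolding, % (v/v).
    temperature_k:
        Absolute temperature of the isothermal slice, K.
    """

    alpha_f: float
    beta_f: float
    alpha_u: float
    beta_u: float
    m_folding: float
    c_u50: float
    temperature_k: float

    def __post_init__(self) -> None:
        for name in ("alpha_f", "beta_f", "alpha_u", "beta_u", "m_folding", "c_u50"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")
        if self.c_u50 > 100:
            raise ParameterError(f"c_u50 must be <= 100 %(v/v), got {self.c_u50}")
        t = _require_finite("temperature_k", self.temperature_k)
        if t <= 0:
            raise ParameterError(f"temperature_k must be > 0, got {t}")

    @classmethod
    def from_celsius(cls, *, temperature_c: float, **kwargs) -> "UnfoldingModelParams":
        return cls(temperature_k=celsius_to_kelvin(temperature_c), **kwargs)

    @property
    def temperature_c(self) -> float:
        return kelvin_to_celsius(self.temperature_k)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d.pop("temperature_k")
        d["temperature_C"] = self.temperature_c
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "UnfoldingModelParams":
        d = dict(d)
        t_c = d.pop("temperature_C")
        return cls(temperature_k=celsius_to_kelvin(t_c), **d)

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict())

    @classmethod
    def from_json(cls, s: str) -> "UnfoldingModelParams":
        return cls.from_json_dict(json.loads(s))


@dataclass(frozen=True)
class ActivityModelParams:
    """Parameters of the activity-solvent model.

    Attributes
    ----------
    xi:
        Scale of the Gaussian boost term (activity units x % (v/v)).
    nu:
        Scale of the two-state (logistic decay) term (activity units).
    sigma:
        Gaussian width: how narrow the tolerated concentration range is,
        % (v/v). Bounded below by 10.
    c_a_max:
        Concentration of maximal activity (Gaussian peak), % (v/v).
    c_a50:
        Concentration of largest activity loss (logistic midpoint), % (v/v).
    m_folding:
        As in :class:`UnfoldingModelParams`; not sign-restricted here.
    temperature_k:
        Absolute temperature, K.
    """

    xi: float
    nu: float
    sigma: float
    c_a_max: float
    c_a50: float
    m_folding: float
    temperature_k: float

    def __post_init__(self) -> None:
        for name in ("xi", "nu", "c_a_max", "c_a50"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")
        _require_finite("m_folding", self.m_folding)
        s = _require_finite("sigma", self.sigma)
        if s < 10:
            raise ParameterError(f"sigma must be >= 10 %(v/v), got {s}")
        if self.c_a_max > 100:
            raise ParameterError(f"c_a_max must be <= 100 %(v/v), got {self.c_a_max}")
        if self.c_a50 > 100:
            raise ParameterError(f"c_a50 must be <= 100 %(v/v), got {self.c_a50}")
        t = _require_finite("temperature_k", self.temperature_k)
        if t <= 0:
            raise ParameterError(f"temperature_k must be > 0, got {t}")

    @classmethod
    def from_celsius(cls, *, temperature_c: float, **kwargs) -> "ActivityModelParams":
        return cls(temperature_k=celsius_to_kelvin(temperature_c), **kwargs)

    @property
    def temperature_c(self) -> float:
        return kelvin_to_celsius(self.temperature_k)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d.pop("temperature_k")
        d["temperature_C"] = self.temperature_c
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "ActivityModelParams":
        d = dict(d)
        t_c = d.pop("temperature_C")
        return cls(temperature_k=celsius_to_kelvin(t_c), **d)

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict())

    @classmethod
    def from_json(cls, s: str) -> "ActivityModelParams":
        return cls.from_json_dict(json.loads(s))


def _check_conc(c_solv) -> np.ndarray:
    c = np.asarray(c_solv, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ParameterError("c_solv must be finite")
    if np.any(c < 0):
        raise ParameterError("c_solv must be >= 0 %(v/v)")
    return c


def eval_fraction_unfolded(params: UnfoldingModelParams, c_solv):
    """Unfolded fraction [U] / ([U] + [F]) at co-solvent concentration c.

    The fraction follows E / (1 + E) with
    E = exp(m_folding / (R T) * (c - c_u50)); it is 0.5 at c = c_u50 and
    monotone nondecreasing in c for m_folding > 0.
    """
    c = _check_conc(c_solv)
    x = params.m_folding / (R_GAS * params.temperature_k) * (c - params.c_u50)
    return _stable_logistic(x)


def eval_unfolding_signal(params: UnfoldingModelParams, c_solv):
    """Spectroscopic signal of the extended two-state unfolding model.

    Population-weighted mix of the two linear baselines:
    (1 - f) * (alpha_f + beta_f c) + f * (alpha_u + beta_u c), with f the
    unfolded fraction. This is algebraically identical to the quotient
    form [alpha_f + beta_f c + (alpha_u + beta_u c) E] / (1 + E) but stays
    finite for arbitrarily large exponents.
    """
    c = _check_conc(c_solv)
    f = eval_fraction_unfolded(params, c)
    folded = params.alpha_f + params.beta_f * c
    unfolded = params.alpha_u + params.beta_u * c
    out = (1.0 - np.asarray(f)) * folded + np.asarray(f) * unfolded
    if np.ndim(c_solv) == 0:
        return float(out)
    return out


def eval_activity(params: ActivityModelParams, c_solv):
    """Activity predicted by the activity-solvent model.

    Gaussian boost plus logistic decay::

        xi * N(c; c_a_max, sigma) + nu * E' / (1 + E'),
        E' = exp(-(m_folding / (R T)) * (c - c_a50))

    Note the negative sign in the exponent: the second term decays with
    increasing co-solvent concentration (for m_folding > 0), mirroring the
    loss of activity as the enzyme unfolds.
    """
    c = _check_conc(c_solv)
    z = (c - params.c_a_max) / params.sigma
    gauss = params.xi / (params.sigma * math.sqrt(2.0 * math.pi)) * np.exp(-0.5 * z * z)
    x = -params.m_folding / (R_GAS * params.temperature_k) * (c - params.c_a50)
    logistic = params.nu * np.asarray(_stable_logistic(x))
    out = gauss + logistic
    if np.ndim(c_solv) == 0:
        return float(out)
    return out


def free_energy_of_folding(params: UnfoldingModelParams, c_solv):
    """Free energy of folding, m_folding * (c_u50 - c), in J mol^-1.

    Positive below c_u50 (folded state favoured), exactly zero at the half
    unfolding concentration, negative above it.
    """
    c = _check_conc(c_solv)
    out = params.m_folding * (params.c_u50 - c)
    if np.ndim(c_solv) == 0:
        return float(out)
    return out
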