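"""Type-2 load variable: instantaneous metabolic power via the
equivalent-slope energy-cost model, and energy per power category.

Accelerated running on flat ground is modeled as uphill running at the
equivalent slope ES = a/g.  The energy cost of running at that slope is a
fifth-order polynomial in ES multiplied by the equivalent mass
EM = sqrt(ES^2 + 1) and a terrain constant KT (1.29 for grass):

    EC(ES) = (155.4 ES^5 - 30.4 ES^4 - 43.3 ES^3 + 46.3 ES^2
              + 19.5 ES + 3.6) * EM * KT        [J kg^-1 m^-1]

Metabolic power is P = EC * v (W/kg).  ES is clipped to +-1 and EC floored
at 0 to guard against differentiation spikes; both guards are configurable.
Energy increments P * dt are accumulated per power band: LP [0, 10),
IP [10, 20), HP [20, 35), EP [35, 55), MP [55, inf) W/kg, reported in
kJ/kg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .time_motion import KinematicSeries

__all__ = [
    "POWER_BAND_NAMES",
    "PowerBands",
    "EnergyModelParams",
    "PowerSeries",
    "equivalent_slope",
    "energy_cost",
    "metabolic_power",
    "energy_by_power_category",
]

POWER_BAND_NAMES = ("lp", "ip", "hp", "ep", "mp")

G = 9.81  # m/s^2


@dataclass(frozen=True)
class PowerBands:
    """Half-open power bands in W/kg; a tie joins the upper band."""

    edges_wkg: tuple[float, ...] = (10.0, 20.0, 35.0, 55.0)

    def bucket_of(self, p_wkg: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.edges_wkg, np.asarray(p_wkg), side="right")


@dataclass(frozen=True)
class EnergyModelParams:
    g: float = G
    kt: float = 1.29  # terrain constant, grass
    #: energy-cost polynomial coefficients (c5..c0), J kg^-1 m^-1
    ec_coeffs: tuple[float, ...] = (155.4, -30.4, -43.3, 46.3, 19.5, 3.6)
    es_clip: float = 1.0  # symmetric clipping bound on the equivalent slope

    def __post_init__(self):
        if self.kt <= 0:
            raise ValueError("terrain constant must be > 0")
        if self.ec_coeffs[-1] <= 0:
            raise ValueError("level-running cost (constant coefficient) must be > 0")


@dataclass
class PowerSeries:
    t: np.ndarray
    es: np.ndarray  # equivalent slope, unitless
    em: np.ndarray  # equivalent mass, >= 1
    ec: np.ndarray  # J kg^-1 m^-1
    p: np.ndarray  # W/kg, >= 0
    dt: float


def equivalent_slope(a, params: EnergyModelParams | None = None) -> np.ndarray:
    """ES = a / g, clipped to [-es_clip, +es_clip]."""
    params = params or EnergyModelParams()
    return np.clip(np.asarray(a, dtype=float) / params.g, -params.es_clip, params.es_clip)


def energy_cost(es, params: EnergyModelParams | None = None) -> np.ndarray:
    """Energy cost of running at equivalent slope ES, floored at 0."""
    params = params or EnergyModelParams()
    es = np.asarray(es, dtype=float)
    em = np.sqrt(es**2 + 1.0)
    ec = np.polyval(params.ec_coeffs, es) * em * params.kt
    return np.maximum(ec, 0.0)


def metabolic_power(series: KinematicSeries, params: EnergyModelParams | None = None) -> PowerSeries:
    """Per-sample metabolic power P = EC(ES(a)) * v."""
    params = params or EnergyModelParams()
    es = equivalent_slope(series.a, params)
    em = np.sqrt(es**2 + 1.0)
    ec = energy_cost(es, params)
    p = ec * series.v
    return PowerSeries(t=series.t, es=es, em=em, ec=ec, p=p, dt=series.dt)


def energy_by_power_category(
    power: PowerSeries,
    bands: PowerBands | None = None,
    idx: np.ndarray | slice = slice(None),
) -> np.ndarray:
    """Energy (kJ/kg) per band [LP, IP, HP, EP, MP] over a sample slice.

    The bands cover [0, inf), so the five entries sum exactly to the total
    energy expenditure of the slice.
    """
    bands = bands or PowerBands()
    p = power.p[idx]
    bucket = bands.bucket_of(p)
    out = np.zeros(len(POWER_BAND_NAMES))
    np.add.at(out, bucket, p * power.dt / 1000.0)
    return out
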