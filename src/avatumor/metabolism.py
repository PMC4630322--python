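"""ATP metabolism and the cell health function.

The model's central quantity is a per-cell, dimensionless "health level" h:
the cell's ATP balance normalized by the ATP production of a fully supplied
quiescent cell (H_Q).  Absorbed glucose follows two pathways: the fraction
that can pair with oxygen at 6 O2 : 1 glucose burns aerobically (30 ATP per
glucose); the remainder ferments anaerobically (2 ATP per glucose) — the
Warburg partition.  Per hour the health level gains the normalized ATP
production and loses a constant decay D = 1 (calibrated so a fully supplied
quiescent cell is in exact energy balance).

State rules: h > 1.5 -> proliferating, h < 0.5 -> necrotic (irreversible),
otherwise quiescent; a proliferating cell becomes eligible for mitosis at
the target h = H_P / H_Q (~2.105).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "CellState",
    "MetabolicRateTable",
    "AtpStoichiometry",
    "AtpYield",
    "HealthState",
    "atp_yield",
    "demand_scaling",
    "health_update",
    "classify_state",
    "waste_from_atp",
]


class CellState(IntEnum):
    """The three classical multicellular-spheroid cell states."""

    PROLIFERATING = 0
    QUIESCENT = 1
    NECROTIC = 2


# Table of per-state metabolic rates (EMT6/Ro-derived).  Oxygen/glucose/waste
# in mM/h/cm^3, growth factor and inhibitor in %/h/cm^3 (treated as ordinary
# concentration rates).  Consumption entries are demands (maxima); realized
# uptake is demand x local availability.
_DEFAULT_RATES = {
    CellState.PROLIFERATING: {
        "oxygen": 108.0, "glucose": 162.0, "waste": 240.0,
        "growth_factor": 1.0, "growth_inhibitor": 0.0,
    },
    CellState.QUIESCENT: {
        "oxygen": 50.0, "glucose": 80.0, "waste": 110.0,
        "growth_factor": 0.5, "growth_inhibitor": 1.0,
    },
    CellState.NECROTIC: {
        "oxygen": 0.0, "glucose": 0.0, "waste": 0.0,
        "growth_factor": 0.0, "growth_inhibitor": 2.0,
    },
}

#: Species consumed by cells (sinks); the rest are produced (sources).
CONSUMED_SPECIES = ("oxygen", "glucose")
PRODUCED_SPECIES = ("waste", "growth_factor", "growth_inhibitor")


@dataclass(frozen=True)
class MetabolicRateTable:
    """Per-state, per-species metabolic rates."""

    rates: dict = field(default_factory=lambda: {s: dict(r) for s, r in _DEFAULT_RATES.items()})

    def __post_init__(self):
        for state, row in self.rates.items():
            for species, rate in row.items():
                if rate < 0:
                    raise InvalidParameterError(f"rate[{state}][{species}] must be >= 0")
        necrotic = self.rates[CellState.NECROTIC]
        for species, rate in necrotic.items():
            if species != "growth_inhibitor" and rate != 0.0:
                raise InvalidParameterError("necrotic cells only produce growth inhibitor")

    def rate(self, state: CellState, species_name: str) -> float:
        return float(self.rates[CellState(state)][species_name])

    def demand_vector(self, states: np.ndarray, species_name: str) -> np.ndarray:
        """Vector of rates for an integer state array."""
        lut = np.array([self.rates[CellState(s)][species_name] for s in range(3)])
        return lut[np.asarray(states, dtype=int)]


@dataclass(frozen=True)
class AtpStoichiometry:
    """Stoichiometric constants of the two-pathway glucose metabolism."""

    oxygen_per_glucose_aerobic: float = 6.0
    atp_per_glucose_aerobic: float = 30.0
    atp_per_glucose_anaerobic: float = 2.0
    atp_per_waste: float = 3.5

    def __post_init__(self):
        if min(self.oxygen_per_glucose_aerobic, self.atp_per_glucose_aerobic,
               self.atp_per_glucose_anaerobic, self.atp_per_waste) <= 0:
            raise InvalidParameterError("stoichiometric constants must be positive")
        if self.atp_per_glucose_aerobic <= self.atp_per_glucose_anaerobic:
            raise InvalidParameterError("aerobic ATP yield must exceed anaerobic yield")


@dataclass(frozen=True)
class AtpYield:
    """ATP production split for one cell over one unit of time.

    All rates in mM/h/cm^3 (face values of the rate table).
    """

    e1_aerobic: float
    e2_anaerobic: float
    glucose_aerobic: float
    glucose_anaerobic: float

    @property
    def total(self) -> float:
        return self.e1_aerobic + self.e2_anaerobic


@dataclass(frozen=True)
class HealthState:
    """Constants of the health function."""

    h_proliferating: float = 828.0       # H_P: ATP rate of a fully fed proliferating cell
    h_quiescent: float = 393.4           # H_Q: ATP rate of a fully fed quiescent cell
    decay: float = 1.0                   # normalized energy decay D per hour
    necrosis_threshold: float = 0.5
    proliferation_threshold: float = 1.5

    def __post_init__(self):
        if self.h_quiescent <= 0 or self.h_proliferating <= self.h_quiescent:
            raise InvalidParameterError("require H_P > H_Q > 0")
        if not self.necrosis_threshold < self.proliferation_threshold < self.mitosis_target:
            raise InvalidParameterError("thresholds must order: necrosis < proliferation < mitosis target")

    @property
    def mitosis_target(self) -> float:
        """Health level at which a proliferating cell may divide (H_P / H_Q)."""
        return self.h_proliferating / self.h_quiescent

    @property
    def proliferation_margin(self) -> float:
        """Extra ATP rate needed to proliferate beyond quiescent maintenance."""
        return self.h_proliferating - self.h_quiescent


def atp_yield(
    oxygen_supplied: float,
    glucose_supplied: float,
    stoich: AtpStoichiometry | None = None,
    aerobic_glucose_ndigits: int | None = None,
) -> AtpYield:
    """Split supplied oxygen and glucose into aerobic and anaerobic ATP.

    Inputs are realized uptake rates, already capped at the state's demand.
    ``aerobic_glucose_ndigits`` optionally rounds the aerobic glucose before
    the anaerobic split, mirroring the printed worked examples (the quiescent
    example carries 50/6 -> 8.3 into a remainder of 71.7).
    """
    if stoich is None:
        stoich = AtpStoichiometry()
    if oxygen_supplied < 0 or glucose_supplied < 0:
        raise InvalidParameterError("supplied rates must be non-negative")
    glucose_aerobic = min(glucose_supplied, oxygen_supplied / stoich.oxygen_per_glucose_aerobic)
    e1 = stoich.atp_per_glucose_aerobic * glucose_aerobic
    split = glucose_aerobic
    if aerobic_glucose_ndigits is not None:
        split = round(glucose_aerobic, aerobic_glucose_ndigits)
    glucose_anaerobic = max(glucose_supplied - split, 0.0)
    e2 = stoich.atp_per_glucose_anaerobic * glucose_anaerobic
    return AtpYield(e1, e2, glucose_aerobic, glucose_anaerobic)


def atp_total_vector(
    oxygen_supplied: np.ndarray,
    glucose_supplied: np.ndarray,
    stoich: AtpStoichiometry | None = None,
) -> np.ndarray:
    """Vectorized total ATP rate for arrays of supplied oxygen and glucose."""
    if stoich is None:
        stoich = AtpStoichiometry()
    o = np.asarray(oxygen_supplied, dtype=float)
    g = np.asarray(glucose_supplied, dtype=float)
    aer = np.minimum(g, o / stoich.oxygen_per_glucose_aerobic)
    return stoich.atp_per_glucose_aerobic * aer + stoich.atp_per_glucose_anaerobic * (g - aer)


def demand_scaling(field_value, boundary_value: float):
    """Fraction of a species demand a cell realizes at the local concentration.

    Linear saturation: clamp(field / boundary, 0, 1).  Scalar or array input.
    """
    if boundary_value <= 0:
        raise ConfigurationError("consumed species require a positive boundary value")
    out = np.clip(np.asarray(field_value, dtype=float) / boundary_value, 0.0, 1.0)
    return float(out) if np.isscalar(field_value) else out


def health_update(h_prev, atp: AtpYield | float, dt: float = 1.0,
                  hs: HealthState | None = None):
    """One health-level step: h + (E1 + E2)/H_Q - D dt.

    ``atp`` may be an :class:`AtpYield` or a precomputed total ATP rate
    (scalar or array, matching ``h_prev``).
    """
    if hs is None:
        hs = HealthState()
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    total = atp.total if isinstance(atp, AtpYield) else atp
    return h_prev + total / hs.h_quiescent - hs.decay * dt


def classify_state(h, current_state=CellState.QUIESCENT, hs: HealthState | None = None):
    """State from health level; necrosis is irreversible.

    Scalar in, scalar out; array in, array out.
    """
    if hs is None:
        hs = HealthState()
    h_arr = np.asarray(h, dtype=float)
    s_arr = np.asarray(current_state, dtype=int)
    out = np.where(h_arr > hs.proliferation_threshold,
                   int(CellState.PROLIFERATING),
                   np.where(h_arr < hs.necrosis_threshold,
                            int(CellState.NECROTIC), int(CellState.QUIESCENT)))
    out = np.where(s_arr == int(CellState.NECROTIC), int(CellState.NECROTIC), out)
    if np.isscalar(h) or np.ndim(h) == 0:
        return CellState(int(out))
    return out.astype(np.int8)


def waste_from_atp(total_atp_rate: float, stoich: AtpStoichiometry | None = None) -> float:
    """Waste rate implied by ATP production (1 waste per 3.5 ATP).

    A consistency check against the rate table's waste rows (which win as the
    primary source term); the two agree to within a few percent.
    """
    if stoich is None:
        stoich = AtpStoichiometry()
    if total_atp_rate < 0:
        raise InvalidParameterError("ATP rate must be non-negative")
    return total_atp_rate / stoich.atp_per_waste
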