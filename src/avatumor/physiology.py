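"""Physiological constants and boundary-value derivations.

The simulator's Dirichlet boundary concentrations are not free knobs: the
oxygen value descends from hemoglobin physiology (mass-to-molar conversion,
tissue hematocrit, oxyphoric power, and the Hill saturation relation between
plasma and blood oxygen), and this module houses that derivation chain
together with every printed constant, loadable from a versioned JSON
parameter file.

Units note: concentrations follow the source data's face values, which label
mol/L-scale numbers as "mM/cm^3" (a dimensionally redundant spelling).  We
keep a single internal concentration unit ("model-mM") equal to those face
values and convert only at the I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidParameterError, SingularInputError, NoRootError

__all__ = [
    "PhysiologicalConstants",
    "BoundaryConditions",
    "hgb_mass_to_molar",
    "tissue_hgb",
    "blood_oxygen",
    "hill_blood_from_plasma",
    "invert_hill",
    "load_default_parameters",
    "round_printed",
]


def round_printed(value: float, ndigits: int) -> float:
    """Round half away from zero at the printed precision.

    Python's builtin ``round`` is banker's rounding; printed tables in the
    physiology literature round half away from zero, so comparisons against
    printed values go through this helper.
    """
    factor = 10.0 ** ndigits
    return float(np.sign(value) * np.floor(abs(value) * factor + 0.5) / factor)


@dataclass(frozen=True)
class PhysiologicalConstants:
    """Printed constants of the oxygen-transport derivation.

    Attributes
    ----------
    hgb_molecular_weight : g/mol
        Molecular weight of hemoglobin.
    hgb_blood_concentration_range : (g/L, g/L)
        Hemoglobin mass concentration range in adult female blood.
    large_vessel_hgb_molar : model-mM
        Hemoglobin molar concentration assumed in large vessels.
    tissue_hematocrit_ratio : dimensionless
        Breast-tissue to large-vessel hematocrit ratio.
    oxyphoric_power : int
        O2 molecules carried per fully saturated hemoglobin.
    blood_saturation : fraction
        Assumed arteriole hemoglobin saturation in breast tissue.
    hill_coefficient : dimensionless
        Hill cooperativity coefficient of hemoglobin.
    p50 : mmHg
        Oxygen partial pressure at 50 % hemoglobin saturation.
    solubility_alpha : mmol L^-1 mmHg^-1
        Oxygen solubility coefficient in plasma.
    blood_hgb_o2 : model-mM
        Tetra-hemoglobin bound-oxygen capacity term [HB] entering the Hill
        relation (the tissue blood-oxygen value 0.0016 x 4 x 0.75).
    """

    hgb_molecular_weight: float = 64450.0
    hgb_blood_concentration_range: tuple[float, float] = (122.0, 150.0)
    large_vessel_hgb_molar: float = 0.002
    tissue_hematocrit_ratio: float = 0.8
    oxyphoric_power: int = 4
    blood_saturation: float = 0.75
    hill_coefficient: float = 2.73
    p50: float = 26.0
    solubility_alpha: float = 1.39e-3
    blood_hgb_o2: float = 0.0048

    def __post_init__(self):
        values = asdict(self)
        rng = values.pop("hgb_blood_concentration_range")
        if any(v <= 0 for v in list(values.values()) + list(rng)):
            raise InvalidParameterError("all physiological constants must be positive")
        if not 0 < self.blood_saturation <= 1:
            raise InvalidParameterError("blood_saturation must lie in (0, 1]")
        if not 0 < self.tissue_hematocrit_ratio <= 1:
            raise InvalidParameterError("tissue_hematocrit_ratio must lie in (0, 1]")


@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet boundary and initial concentrations per species (model-mM).

    Waste, growth factor and growth inhibitor are produced by the tumor and
    diluted away by circulation, so their far-field values are exactly zero.
    Initial values default to the boundary values (uniform start).
    """

    oxygen: float = 0.00053
    glucose: float = 0.005
    waste: float = 0.0
    growth_factor: float = 0.0
    growth_inhibitor: float = 0.0
    initial: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("oxygen", "glucose", "waste", "growth_factor", "growth_inhibitor"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"boundary value for {name} must be non-negative")
        for name in ("waste", "growth_factor", "growth_inhibitor"):
            if getattr(self, name) != 0.0:
                raise InvalidParameterError(f"{name} boundary value must be exactly zero")

    def boundary_value(self, species_name: str) -> float:
        return float(getattr(self, species_name))

    def initial_value(self, species_name: str) -> float:
        return float(self.initial.get(species_name, getattr(self, species_name)))


def hgb_mass_to_molar(concentration_g_per_l: float, mw: float = 64450.0) -> float:
    """Convert hemoglobin mass concentration (g/L) to molar face value.

    The source data quotes the result in "mM/cm^3" face values that equal
    g/L divided by g/mol (122 g/L -> 0.0019); that convention is preserved.
    """
    if mw <= 0:
        raise InvalidParameterError("molecular weight must be positive")
    if concentration_g_per_l < 0:
        raise InvalidParameterError("concentration must be non-negative")
    return concentration_g_per_l / mw


def tissue_hgb(large_vessel_hgb: float, hematocrit_ratio: float) -> float:
    """Hemoglobin concentration in tissue blood from the large-vessel value."""
    if not 0 < hematocrit_ratio <= 1:
        raise InvalidParameterError("hematocrit ratio must lie in (0, 1]")
    return large_vessel_hgb * hematocrit_ratio


def blood_oxygen(hgb_molar: float, oxyphoric_power: int = 4, saturation: float = 0.75) -> float:
    """Bound oxygen concentration in blood: [Hgb] x carrying power x saturation."""
    if not 0 <= saturation <= 1:
        raise InvalidParameterError("saturation must lie in [0, 1]")
    return hgb_molar * oxyphoric_power * saturation


def hill_blood_from_plasma(c_plasma: float, consts: PhysiologicalConstants | None = None) -> float:
    """Total blood oxygen from plasma oxygen via the Hill saturation relation.

    C_B = C_P + [HB] P_O2 / (1 + (alpha P50 / C_P)^h)

    Monotone increasing in C_P; tends to C_P as C_P -> 0+ and to
    C_P + [HB] P_O2 at saturation.
    """
    if consts is None:
        consts = PhysiologicalConstants()
    if c_plasma <= 0:
        raise SingularInputError("plasma oxygen concentration must be strictly positive")
    sat = 1.0 + (consts.solubility_alpha * consts.p50 / c_plasma) ** consts.hill_coefficient
    return c_plasma + consts.blood_hgb_o2 * consts.oxyphoric_power / sat


def invert_hill(
    c_blood_target: float,
    consts: PhysiologicalConstants | None = None,
    tol: float = 1e-9,
) -> float:
    """Numerically invert :func:`hill_blood_from_plasma` for a target C_B.

    Verifies monotonicity of the forward map on a log-spaced grid before
    bisecting; raises :class:`NoRootError` for unattainable targets.
    """
    if consts is None:
        consts = PhysiologicalConstants()
    lo, hi = 1e-12, 1e3
    grid = np.geomspace(lo, hi, 200)
    fwd = np.array([hill_blood_from_plasma(x, consts) for x in grid])
    if not np.all(np.diff(fwd) > 0):
        raise NoRootError("forward Hill map is not strictly increasing on the search range")
    f_lo = hill_blood_from_plasma(lo, consts)
    f_hi = hill_blood_from_plasma(hi, consts)
    if not f_lo <= c_blood_target <= f_hi:
        raise NoRootError(
            f"target {c_blood_target} outside attainable blood-oxygen range [{f_lo:.3g}, {f_hi:.3g}]"
        )
    root = brentq(lambda x: hill_blood_from_plasma(x, consts) - c_blood_target, lo, hi, xtol=tol)
    return float(root)


def load_default_parameters() -> dict:
    """Load the versioned flat key->value parameter file shipped with the package."""
    with resources.files("avatumor.data").joinpath("defaults.json").open() as fh:
        return json.load(fh)
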