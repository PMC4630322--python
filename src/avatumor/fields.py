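"""Discretized biochemical concentration fields over the tumor domain.

Five species (oxygen, glucose, waste, growth factor, growth inhibitor)
diffuse through the extracellular fluid with Dirichlet far-field values and
per-cell source/sink terms:

    dC_i/dt - div(D_i grad C_i) = Q_i

The domain is a regular rectangular grid with an inscribed circular (2-D) or
spherical (3-D) mask: nodes outside the mask, and all array-edge nodes, are
Dirichlet boundary nodes.  Cells live off-lattice; coupling uses cloud-in-cell
(multilinear) deposition and interpolation.

Two integrators are provided: an explicit scheme with an enforced stability
contract (optionally sub-cycled), and an unconditionally stable backward-Euler
scheme with optional linearized uptake sinks used by the simulation engine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field, replace
from enum import IntEnum

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .errors import InvalidParameterError, OutOfDomainError, StepSizeError
from .metabolism import CONSUMED_SPECIES, MetabolicRateTable
from .physiology import BoundaryConditions

__all__ = [
    "SpeciesId",
    "DomainGrid",
    "SpeciesField",
    "DEFAULT_DIFFUSION",
    "initialize_fields",
    "diffusion_step",
    "implicit_step",
    "deposit_sources",
    "uptake_coefficients",
    "sample_concentration",
    "sample_gradient",
]


class SpeciesId(IntEnum):
    """The five biochemical species, in their canonical order."""

    OXYGEN = 0
    GLUCOSE = 1
    WASTE = 2
    GROWTH_FACTOR = 3
    GROWTH_INHIBITOR = 4

    @property
    def key(self) -> str:
        return self.name.lower()


#: Diffusion constants (cm^2/h), experimentally derived.
DEFAULT_DIFFUSION = {
    SpeciesId.OXYGEN: 5.94e-2,
    SpeciesId.GLUCOSE: 1.52e-3,
    SpeciesId.WASTE: 2.124e-3,
    SpeciesId.GROWTH_FACTOR: 1e-6,
    SpeciesId.GROWTH_INHIBITOR: 1e-6,
}


class DomainGrid:
    """Regular grid over a rectangular box with an inscribed round domain.

    Parameters
    ----------
    extent : float or sequence of float
        Physical side length(s) of the box in cm.
    nodes : int or sequence of int
        Node count per axis.
    dim : int
        2 or 3.
    circular : bool
        If True (default), the domain boundary is the inscribed
        circle/sphere; nodes outside it are Dirichlet nodes.  Array-edge
        nodes are always Dirichlet nodes.
    """

    def __init__(self, extent=0.4, nodes=200, dim: int = 2, circular: bool = True):
        if dim not in (2, 3):
            raise InvalidParameterError("dimensionality must be 2 or 3")
        self.dim = dim
        self.extent = np.broadcast_to(np.asarray(extent, dtype=float), (dim,)).copy()
        self.shape = tuple(np.broadcast_to(np.asarray(nodes, dtype=int), (dim,)))
        if np.any(self.extent <= 0) or any(n < 3 for n in self.shape):
            raise InvalidParameterError("extent must be positive and nodes >= 3 per axis")
        self.spacing = self.extent / (np.array(self.shape) - 1)
        self.center = self.extent / 2.0
        self.circular = circular
        self.radius = float(np.min(self.extent)) / 2.0

        coords = np.indices(self.shape).astype(float)
        for ax in range(dim):
            coords[ax] *= self.spacing[ax]
        self._coords = coords
        interior = np.ones(self.shape, dtype=bool)
        for ax in range(dim):
            idx = [slice(None)] * dim
            idx[ax] = 0
            interior[tuple(idx)] = False
            idx[ax] = -1
            interior[tuple(idx)] = False
        if circular:
            r2 = sum((coords[ax] - self.center[ax]) ** 2 for ax in range(dim))
            interior &= r2 < self.radius ** 2
        self.interior = interior
        self.boundary = ~interior
        if not self.boundary.any() or not self.interior.any():
            raise InvalidParameterError("grid must have both interior and boundary nodes")
        self._laplacian = None

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def node_volume(self) -> float:
        return float(np.prod(self.spacing))

    def node_coordinates(self) -> np.ndarray:
        """(dim, *shape) array of physical node coordinates."""
        return self._coords

    def contains(self, positions) -> np.ndarray:
        """Whether points lie inside the domain (strictly inside the mask)."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        inside = np.all((pos >= 0) & (pos <= self.extent), axis=1)
        if self.circular:
            r2 = np.sum((pos - self.center) ** 2, axis=1)
            inside &= r2 <= self.radius ** 2
        return inside if np.ndim(positions) > 1 else bool(inside[0])

    def laplacian(self) -> sp.csr_matrix:
        """Sparse discrete Laplacian with boundary rows zeroed (cached)."""
        if self._laplacian is None:
            mats = []
            for ax, (n, h) in enumerate(zip(self.shape, self.spacing)):
                l1 = sp.diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(n, n)) / h ** 2
                eyes = [sp.identity(m) for m in self.shape]
                eyes[ax] = l1
                term = eyes[0]
                for m in eyes[1:]:
                    term = sp.kron(term, m)
                mats.append(term)
            lap = sum(mats)
            mask = sp.diags(self.interior.ravel().astype(float))
            self._laplacian = (mask @ lap).tocsr()
        return self._laplacian

    def cic_weights(self, positions: np.ndarray):
        """Cloud-in-cell corner indices and weights for off-lattice points.

        Returns (flat_indices, weights), each of shape (n_points, 2**dim);
        weights sum to 1 per point.
        """
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        frac = pos / self.spacing
        i0 = np.floor(frac).astype(int)
        i0 = np.clip(i0, 0, np.array(self.shape) - 2)
        t = frac - i0
        corners = list(itertools.product((0, 1), repeat=self.dim))
        idx = np.empty((pos.shape[0], len(corners)), dtype=np.int64)
        wts = np.empty((pos.shape[0], len(corners)))
        for c, offs in enumerate(corners):
            multi = tuple(i0[:, ax] + offs[ax] for ax in range(self.dim))
            idx[:, c] = np.ravel_multi_index(multi, self.shape)
            w = np.ones(pos.shape[0])
            for ax in range(self.dim):
                w *= t[:, ax] if offs[ax] else 1.0 - t[:, ax]
            wts[:, c] = w
        return idx, wts


@dataclass
class SpeciesField:
    """One species' concentration over the grid (model-mM)."""

    species: SpeciesId
    grid: DomainGrid
    values: np.ndarray
    diffusion_constant: float
    boundary_value: float
    clamped_mass: float = 0.0

    def __post_init__(self):
        if self.diffusion_constant < 0 or self.boundary_value < 0:
            raise InvalidParameterError("diffusion constant and boundary value must be >= 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise InvalidParameterError("field values must match the grid shape")

    def impose_boundary(self) -> None:
        self.values[self.grid.boundary] = self.boundary_value


def initialize_fields(grid: DomainGrid, bc: BoundaryConditions | None = None,
                      diffusion: dict | None = None) -> dict[SpeciesId, SpeciesField]:
    """Uniform initial fields: each species at its initial constant."""
    bc = bc or BoundaryConditions()
    diffusion = {**DEFAULT_DIFFUSION, **(diffusion or {})}
    fields = {}
    for sid in SpeciesId:
        values = np.full(grid.shape, bc.initial_value(sid.key), dtype=float)
        f = SpeciesField(sid, grid, values, diffusion[sid], bc.boundary_value(sid.key))
        f.impose_boundary()
        fields[sid] = f
    return fields


def _laplacian_apply(values: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Dense stencil Laplacian; edge nodes produce garbage that boundary
    re-imposition overwrites (all array-edge nodes are Dirichlet)."""
    out = np.zeros_like(values)
    for ax, h in enumerate(spacing):
        out += (np.roll(values, 1, axis=ax) + np.roll(values, -1, axis=ax)
                - 2.0 * values) / h ** 2
    return out


def stable_dt(grid: DomainGrid, diffusion_constant: float) -> float:
    """Largest explicit-scheme-stable time step for this grid and D."""
    if diffusion_constant == 0:
        return np.inf
    return float(np.min(grid.spacing) ** 2 / (2.0 * grid.dim * diffusion_constant))


def diffusion_step(field: SpeciesField, source: np.ndarray | None, dt: float,
                   subcycle: bool = True, clamp: bool = True) -> SpeciesField:
    """One explicit (FTCS) step of the diffusion PDE with Dirichlet values.

    Refuses steps beyond the stability bound dt <= h^2/(2 dim D) unless
    ``subcycle`` is enabled, in which case the step is split evenly.
    Negative concentrations are clamped to zero with the removed mass logged
    on the returned field's ``clamped_mass``.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    grid = field.grid
    limit = stable_dt(grid, field.diffusion_constant)
    if dt > limit * (1 + 1e-12):
        if not subcycle:
            raise StepSizeError(
                f"dt={dt} exceeds explicit stability limit {limit:.3g}; "
                "enable subcycling or reduce dt")
        n_sub = int(np.ceil(dt / limit))
    else:
        n_sub = 1
    h = dt / n_sub
    values = field.values.copy()
    clamped = 0.0
    src = 0.0 if source is None else np.asarray(source, dtype=float)
    for _ in range(n_sub):
        rhs = src + field.diffusion_constant * _laplacian_apply(values, grid.spacing)
        values = values + h * np.where(grid.interior, rhs, 0.0)
        values[grid.boundary] = field.boundary_value
        if clamp:
            neg = values < 0
            if neg.any():
                clamped += float(-values[neg].sum()) * grid.node_volume
                values[neg] = 0.0
    return replace(field, values=values, clamped_mass=field.clamped_mass + clamped)


def implicit_step(field: SpeciesField, source: np.ndarray | None, dt: float,
                  uptake: np.ndarray | None = None) -> SpeciesField:
    """One backward-Euler step, optionally with a linearized uptake sink.

    Solves (I - dt D L + dt diag(k)) C' = C + dt Q on interior nodes with
    Dirichlet rows pinned to the boundary value.  ``uptake`` is a per-node
    sink coefficient k (1/h) so consumption -k C' is treated implicitly —
    unconditionally stable and sign-preserving even for stiff sinks.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    grid = field.grid
    n = grid.n_nodes
    interior = grid.interior.ravel()
    a = sp.identity(n, format="csr") - dt * field.diffusion_constant * grid.laplacian()
    if uptake is not None:
        k = np.asarray(uptake, dtype=float).ravel()
        a = a + sp.diags(np.where(interior, dt * k, 0.0))
    rhs = field.values.ravel().copy()
    if source is not None:
        rhs = rhs + dt * np.asarray(source, dtype=float).ravel() * interior
    rhs[~interior] = field.boundary_value
    values = spsolve(a.tocsc(), rhs).reshape(grid.shape)
    clamped = 0.0
    neg = values < 0
    if neg.any():  # cannot occur for pure sinks (M-matrix), only odd sources
        clamped = float(-values[neg].sum()) * grid.node_volume
        values[neg] = 0.0
    values[grid.boundary] = field.boundary_value
    return replace(field, values=values, clamped_mass=field.clamped_mass + clamped)


def _cell_amplitudes(positions, radii, grid: DomainGrid):
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if not np.all(grid.contains(pos)):
        raise OutOfDomainError("all cells must lie inside the domain")
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (pos.shape[0],))
    if grid.dim == 2:
        vol = np.pi * radii ** 2
    else:
        vol = 4.0 / 3.0 * np.pi * radii ** 3
    return pos, vol / grid.node_volume


def deposit_sources(cells, grid: DomainGrid, rates: MetabolicRateTable | None = None,
                    fields: dict | None = None, gain: float = 1.0,
                    signal_gain: float | None = None) -> dict[SpeciesId, np.ndarray]:
    """Assemble per-species net source densities (model-mM per hour) from cells.

    Each cell contributes its state's table rate, scaled by the dimensionless
    coupling ``gain`` and its volume fraction of the overlapped nodes,
    distributed with cloud-in-cell weights (conserving the cell total).
    Consumption (oxygen, glucose) enters negative and — when current
    ``fields`` are supplied — is further scaled by local availability
    (``demand_scaling``); production enters positive and unscaled.
    ``signal_gain`` optionally decouples the growth factor/inhibitor coupling
    strength from the nutrient one.

    ``cells`` is anything exposing ``positions`` (n, dim), ``radii`` (n,) and
    ``states`` (n,) arrays (see :class:`avatumor.cells.CellPopulation`).
    """
    from .metabolism import demand_scaling  # local import avoids cycle at module load

    rates = rates or MetabolicRateTable()
    if signal_gain is None:
        signal_gain = gain
    positions = getattr(cells, "positions")
    states = np.asarray(getattr(cells, "states"), dtype=int)
    radii = getattr(cells, "radii")
    out = {sid: np.zeros(grid.shape) for sid in SpeciesId}
    if len(states) == 0:
        return out
    pos, volfrac = _cell_amplitudes(positions, radii, grid)
    idx, wts = grid.cic_weights(pos)
    for sid in SpeciesId:
        demand = rates.demand_vector(states, sid.key)
        g = signal_gain if sid in (SpeciesId.GROWTH_FACTOR, SpeciesId.GROWTH_INHIBITOR) else gain
        amp = demand * g * volfrac
        if sid.key in CONSUMED_SPECIES:
            amp = -amp
            if fields is not None:
                f = fields[sid]
                local = interpolate(grid, f.values, pos)
                amp = amp * demand_scaling(local, f.boundary_value)
        flat = np.zeros(grid.n_nodes)
        np.add.at(flat, idx.ravel(), (amp[:, None] * wts).ravel())
        arr = flat.reshape(grid.shape)
        arr[grid.boundary] = 0.0
        out[sid] = arr
    return out


def uptake_coefficients(cells, grid: DomainGrid, rates: MetabolicRateTable | None = None,
                        bc: BoundaryConditions | None = None,
                        gain: float = 1.0) -> dict[SpeciesId, np.ndarray]:
    """Per-node linear sink coefficients k (1/h) for the consumed species.

    The linear-saturation uptake model -demand * C/C_boundary, deposited with
    the same cloud-in-cell weights as :func:`deposit_sources`, for implicit
    treatment in :func:`implicit_step`.
    """
    rates = rates or MetabolicRateTable()
    bc = bc or BoundaryConditions()
    positions = getattr(cells, "positions")
    states = np.asarray(getattr(cells, "states"), dtype=int)
    radii = getattr(cells, "radii")
    out = {}
    if len(states) == 0:
        return {SpeciesId[k.upper()]: np.zeros(grid.shape) for k in CONSUMED_SPECIES}
    pos, volfrac = _cell_amplitudes(positions, radii, grid)
    idx, wts = grid.cic_weights(pos)
    for key in CONSUMED_SPECIES:
        sid = SpeciesId[key.upper()]
        demand = rates.demand_vector(states, key)
        amp = demand * gain * volfrac / bc.boundary_value(key)
        flat = np.zeros(grid.n_nodes)
        np.add.at(flat, idx.ravel(), (amp[:, None] * wts).ravel())
        arr = flat.reshape(grid.shape)
        arr[grid.boundary] = 0.0
        out[sid] = arr
    return out


def interpolate(grid: DomainGrid, values: np.ndarray, positions) -> np.ndarray:
    """Multilinear interpolation of node values at off-lattice points."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    idx, wts = grid.cic_weights(pos)
    flat = values.ravel()
    out = np.sum(flat[idx] * wts, axis=1)
    return out if np.ndim(positions) > 1 else float(out[0])


def interpolate_gradient(grid: DomainGrid, values: np.ndarray, positions) -> np.ndarray:
    """Central-difference gradient interpolated to off-lattice points (per cm)."""
    grads = np.gradient(values, *grid.spacing)
    if grid.dim == 1:
        grads = [grads]
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    out = np.stack([interpolate(grid, g, pos) for g in grads], axis=1)
    return out if np.ndim(positions) > 1 else out[0]


def sample_concentration(field: SpeciesField, position) -> float:
    """Concentration at an off-lattice position inside the domain."""
    if not np.all(field.grid.contains(np.atleast_2d(position))):
        raise OutOfDomainError("position outside the domain")
    return interpolate(field.grid, field.values, position)


def sample_gradient(field: SpeciesField, position) -> np.ndarray:
    """Concentration gradient vector at an off-lattice position."""
    if not np.all(field.grid.contains(np.atleast_2d(position))):
        raise OutOfDomainError("position outside the domain")
    return interpolate_gradient(field.grid, field.values, position)
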