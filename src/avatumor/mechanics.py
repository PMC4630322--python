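"""Off-lattice cell mechanics.

Differential-adhesion springs: every non-necrotic pair of neighboring cells
attracts with a Hookean force F = -k d along the center line, with state-pair
constants k_PP > k_PQ > k_QQ (pairs involving a necrotic cell are neglected).
Proliferating cells additionally feel a chemotaxis force along
m = alpha grad C_O + beta grad C_G - gamma grad C_W.

Motion is overdamped (viscosity-dominated): displacement = mobility x force
x dt, capped at one cell radius per iteration to forbid unphysical jumps.
Incompressibility is enforced by iterative pairwise projection: overlapping
pairs are pushed apart along their center line, each by half the overlap.

Neighbor search uses uniform spatial hashing (cell-linked bins); it returns
exactly the same pair set as the brute-force O(n^2) scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .fields import DomainGrid, SpeciesId, interpolate_gradient
from .metabolism import CellState

__all__ = [
    "SpringConstants",
    "ChemotaxisWeights",
    "neighbor_pairs",
    "adhesion_forces",
    "chemotaxis_vector",
    "resolve_overlaps",
    "integrate_motion",
]


@dataclass(frozen=True)
class SpringConstants:
    """State-pair adhesion spring constants (model force per cm)."""

    k_pp: float = 1.0
    k_pq: float = 0.5
    k_qq: float = 0.25
    cutoff_factor: float = 1.2  # interaction range as a multiple of summed radii

    def __post_init__(self):
        if min(self.k_pp, self.k_pq, self.k_qq) < 0:
            raise InvalidParameterError("spring constants must be >= 0")
        if self.cutoff_factor < 1:
            raise InvalidParameterError("cutoff factor must be >= 1")

    def for_pair(self, state_a, state_b) -> float:
        """Constant for a state pair; zero if either cell is necrotic."""
        a, b = int(state_a), int(state_b)
        if int(CellState.NECROTIC) in (a, b):
            return 0.0
        n_p = (a == int(CellState.PROLIFERATING)) + (b == int(CellState.PROLIFERATING))
        return (self.k_qq, self.k_pq, self.k_pp)[n_p]


@dataclass(frozen=True)
class ChemotaxisWeights:
    """Positive weights of the oxygen, glucose and waste gradients."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.5

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise InvalidParameterError("chemotaxis weights must be positive")


def neighbor_pairs(positions: np.ndarray, cutoffs, max_cutoff: float | None = None):
    """All pairs (i < j) with center distance <= their pairwise cutoff.

    ``cutoffs`` is either a scalar, or a per-cell array whose pairwise sums
    define the cutoff (pass e.g. ``cutoff_factor * radii``).  Candidate pairs
    come from a k-d tree ball query at the maximum pairwise cutoff, then the
    per-pair criterion is applied exactly — the result matches the O(n^2)
    scan pair-for-pair.  Returns (i, j, distance) arrays.
    """
    from scipy.spatial import cKDTree

    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        z = np.empty(0, dtype=int)
        return z, z.copy(), np.empty(0)
    n = pos.shape[0]
    cut = np.broadcast_to(np.asarray(cutoffs, dtype=float), (n,))
    if max_cutoff is None:
        max_cutoff = 2 * float(cut.max())
    pairs = cKDTree(pos).query_pairs(max(max_cutoff, 1e-300), output_type="ndarray")
    if len(pairs) == 0:
        z = np.empty(0, dtype=int)
        return z, z.copy(), np.empty(0)
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(pos[i] - pos[j], axis=1)
    within = d <= cut[i] + cut[j]
    return i[within], j[within], d[within]


def adhesion_forces(positions, radii, states, springs: SpringConstants | None = None):
    """Net adhesion force on every cell (attractive Hookean springs).

    Coincident centers give no direction and contribute nothing.  Forces obey
    Newton's third law pairwise, so they sum to zero over the population.
    """
    springs = springs or SpringConstants()
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = pos.shape[0]
    forces = np.zeros_like(pos)
    if n < 2:
        return forces
    radii = np.broadcast_to(np.asarray(radii, float), (n,))
    states = np.asarray(states, dtype=int)
    i, j, d = neighbor_pairs(pos, springs.cutoff_factor * radii)
    if len(i) == 0:
        return forces
    k_lut = np.array([
        [springs.k_pp, springs.k_pq, 0.0],
        [springs.k_pq, springs.k_qq, 0.0],
        [0.0, 0.0, 0.0],
    ])
    k = k_lut[states[i], states[j]]
    ok = (d > 0) & (k > 0)
    i, j, d, k = i[ok], j[ok], d[ok], k[ok]
    unit = (pos[j] - pos[i]) / d[:, None]
    f = (k * d)[:, None] * unit  # attraction: i pulled toward j
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)
    return forces


def chemotaxis_vector(position, fields: dict, weights: ChemotaxisWeights | None = None):
    """Nutrient-waste drive m = alpha grad C_O + beta grad C_G - gamma grad C_W.

    Accepts a single position or an (n, dim) array; only proliferating cells
    should be subjected to the resulting force (quiescent and necrotic cells
    are unaffected by taxis).
    """
    weights = weights or ChemotaxisWeights()
    grid = fields[SpeciesId.OXYGEN].grid
    go = interpolate_gradient(grid, fields[SpeciesId.OXYGEN].values, position)
    gg = interpolate_gradient(grid, fields[SpeciesId.GLUCOSE].values, position)
    gw = interpolate_gradient(grid, fields[SpeciesId.WASTE].values, position)
    return weights.alpha * go + weights.beta * gg - weights.gamma * gw


def resolve_overlaps(positions, radii, rng=None, grid: DomainGrid | None = None,
                     tol: float = 0.01, max_iter: int = 60):
    """Iteratively project overlapping cells apart (incompressible bodies).

    Each overlapping pair is pushed apart along the center line, half the
    overlap each; coincident pairs separate along a random (rng) or fixed
    direction.  Terminates when the worst overlap is below ``tol`` x radius
    or the iteration cap is hit (then a warning flag is returned).  Positions
    are clamped inside the domain when a grid is given.

    Returns (positions, info) with info = {"max_overlap", "iterations",
    "converged"}.
    """
    pos = np.array(np.atleast_2d(positions), dtype=float)
    n = pos.shape[0]
    radii = np.broadcast_to(np.asarray(radii, float), (n,)).copy()
    info = {"max_overlap": 0.0, "iterations": 0, "converged": True}
    if n < 2:
        if grid is not None:
            pos = _clamp_inside(pos, radii, grid)
        return pos, info
    rmin = radii.min()
    for it in range(max_iter):
        i, j, d = neighbor_pairs(pos, radii)
        target = radii[i] + radii[j]
        overlap = target - d
        bad = overlap > tol * rmin
        info["iterations"] = it + 1
        if not bad.any():
            info["max_overlap"] = float(max(overlap.max(), 0.0)) if len(overlap) else 0.0
            break
        i, j, d, overlap, target = i[bad], j[bad], d[bad], overlap[bad], target[bad]
        diff = pos[j] - pos[i]
        zero = d <= 1e-15
        if zero.any():
            if rng is not None:
                rd = rng.normal(size=(int(zero.sum()), pos.shape[1]))
            else:
                rd = np.ones((int(zero.sum()), pos.shape[1]))
            rd /= np.linalg.norm(rd, axis=1, keepdims=True)
            diff[zero] = rd * 1e-12
            d = np.where(zero, 1e-12, d)
            overlap = np.where(zero, target, overlap)
        unit = diff / d[:, None]
        push = 0.5 * overlap[:, None] * unit
        delta = np.zeros_like(pos)
        np.add.at(delta, j, push)
        np.add.at(delta, i, -push)
        pos += delta
        if grid is not None:
            pos = _clamp_inside(pos, radii, grid)
    else:
        info["converged"] = False
        i, j, d = neighbor_pairs(pos, radii)
        if len(d):
            info["max_overlap"] = float(max((radii[i] + radii[j] - d).max(), 0.0))
    if grid is not None:
        pos = _clamp_inside(pos, radii, grid)
    return pos, info


def _clamp_inside(pos: np.ndarray, radii: np.ndarray, grid: DomainGrid) -> np.ndarray:
    """Project positions back inside the domain (box and inscribed mask)."""
    pos = np.clip(pos, radii[:, None] * 0 + grid.spacing * 1e-3,
                  grid.extent - grid.spacing * 1e-3)
    if grid.circular:
        rel = pos - grid.center
        dist = np.linalg.norm(rel, axis=1)
        rmax = grid.radius * (1 - 1e-9)
        out = dist > rmax
        if out.any():
            pos[out] = grid.center + rel[out] / dist[out, None] * rmax
    return pos


def integrate_motion(positions, forces, dt: float, mobility: float,
                     max_step: float | None = None):
    """Overdamped first-order update: displacement = mobility x force x dt.

    ``max_step`` caps per-cell displacement magnitude (typically one cell
    radius) to keep motion physical for arbitrary force magnitudes.
    Overlap resolution and domain clamping are applied by the caller.
    """
    if dt <= 0 or mobility < 0:
        raise InvalidParameterError("dt must be positive and mobility >= 0")
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    disp = mobility * np.atleast_2d(np.asarray(forces, dtype=float)) * dt
    if max_step is not None:
        norms = np.linalg.norm(disp, axis=1)
        over = norms > max_step
        if over.any():
            disp[over] *= (max_step / norms[over])[:, None]
    return pos + disp
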