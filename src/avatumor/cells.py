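"""Agent layer: cell registry, stochastic mitosis, stem-cell seeding, dissolution.

Cells are off-lattice disks/spheres with a state (proliferating, quiescent,
necrotic), a health level, a generation count N (mitoses since the founder,
capped by the Hayflick limit of 60) and an accumulated phenotype mutation
count that raises the mean mitosis probability.

Mitosis composes two rules: a deterministic eligibility gate at the target
health H_P/H_Q, then a per-iteration Bernoulli draw with probability
(h - 1) M + eps, M = r (1 + mu)(1 + C_GF - C_GI), eps ~ N(0, sigma^2).
Daughters appear at the mother's position with her health equally divided;
mechanics separates them in the same iteration.

A cancer stem cell random-walks through the domain, exempt from metabolism,
and seeds one fresh proliferating cell every ``spawn_period`` iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError, OutOfDomainError
from .fields import DomainGrid
from .metabolism import CellState, HealthState

__all__ = [
    "Cell",
    "CellPopulation",
    "StemCell",
    "MitosisParams",
    "mitosis_mean",
    "mitosis_probability",
    "attempt_mitosis",
    "stem_cell_step",
    "dissolve_necrotic",
]

#: Default cell radius in cm (eukaryotic diameter ~20 um).
DEFAULT_RADIUS = 1e-3


@dataclass
class Cell:
    """One agent; a record view over :class:`CellPopulation` rows."""

    id: int
    position: np.ndarray
    radius: float = DEFAULT_RADIUS
    state: CellState = CellState.PROLIFERATING
    health: float = 1.0
    generation: int = 0
    mutations: int = 0
    necrosis_time: int | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0:
            raise InvalidParameterError("cell radius must be positive")
        if self.generation < 0 or self.mutations < 0:
            raise InvalidParameterError("generation and mutation counts must be >= 0")
        if self.state == CellState.NECROTIC and self.necrosis_time is None:
            raise InvalidParameterError("necrotic cells must carry a necrosis time")


class CellPopulation:
    """Structure-of-arrays container for the cell population.

    Iterating yields :class:`Cell` records; the engine operates on the
    arrays directly.
    """

    def __init__(self, dim: int = 2):
        self.dim = dim
        self.ids = np.empty(0, dtype=np.int64)
        self.positions = np.empty((0, dim))
        self.radii = np.empty(0)
        self.states = np.empty(0, dtype=np.int8)
        self.health = np.empty(0)
        self.generations = np.empty(0, dtype=np.int32)
        self.mutations = np.empty(0, dtype=np.int32)
        self.necrosis_times = np.empty(0)  # NaN = not necrotic
        self.lineages = np.empty(0, dtype=np.int32)  # 0 = founder, k = k-th stem spawn
        self._next_id = 0

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        for i in range(len(self)):
            yield self.record(i)

    def record(self, i: int) -> Cell:
        nt = self.necrosis_times[i]
        return Cell(
            id=int(self.ids[i]), position=self.positions[i].copy(),
            radius=float(self.radii[i]), state=CellState(int(self.states[i])),
            health=float(self.health[i]), generation=int(self.generations[i]),
            mutations=int(self.mutations[i]),
            necrosis_time=None if np.isnan(nt) else int(nt),
        )

    def add(self, positions, states, health, generations=0, mutations=0,
            radii=DEFAULT_RADIUS, necrosis_times=np.nan, lineages=0) -> np.ndarray:
        """Append cells; returns the new ids."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = positions.shape[0]
        ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        self.ids = np.concatenate([self.ids, ids])
        self.positions = np.vstack([self.positions, positions])
        self.radii = np.concatenate([self.radii, np.broadcast_to(np.asarray(radii, float), (n,))])
        self.states = np.concatenate(
            [self.states, np.broadcast_to(np.asarray(states, np.int8), (n,))])
        self.health = np.concatenate(
            [self.health, np.broadcast_to(np.asarray(health, float), (n,))])
        self.generations = np.concatenate(
            [self.generations, np.broadcast_to(np.asarray(generations, np.int32), (n,))])
        self.mutations = np.concatenate(
            [self.mutations, np.broadcast_to(np.asarray(mutations, np.int32), (n,))])
        self.necrosis_times = np.concatenate(
            [self.necrosis_times, np.broadcast_to(np.asarray(necrosis_times, float), (n,))])
        self.lineages = np.concatenate(
            [self.lineages, np.broadcast_to(np.asarray(lineages, np.int32), (n,))])
        return ids

    def keep(self, mask: np.ndarray) -> None:
        """Retain only the rows where mask is True."""
        mask = np.asarray(mask, dtype=bool)
        for name in ("ids", "positions", "radii", "states", "health",
                     "generations", "mutations", "necrosis_times", "lineages"):
            setattr(self, name, getattr(self, name)[mask])

    def counts(self) -> dict[CellState, int]:
        return {s: int(np.sum(self.states == int(s))) for s in CellState}

    @property
    def living_mask(self) -> np.ndarray:
        return self.states != int(CellState.NECROTIC)

    @classmethod
    def from_cells(cls, cells: list[Cell], dim: int | None = None) -> "CellPopulation":
        dim = dim if dim is not None else (len(cells[0].position) if cells else 2)
        pop = cls(dim=dim)
        for c in cells:
            pop.add(c.position, int(c.state), c.health, c.generation, c.mutations,
                    c.radius, np.nan if c.necrosis_time is None else float(c.necrosis_time))
        return pop

    def to_dataframe(self, iteration: int | None = None):
        import pandas as pd

        df = pd.DataFrame({"id": self.ids})
        for ax, name in enumerate("xyz"[: self.dim]):
            df[name] = self.positions[:, ax]
        df["radius"] = self.radii
        df["state"] = [CellState(int(s)).name.lower() for s in self.states]
        df["health"] = self.health
        df["generation"] = self.generations
        df["mutations"] = self.mutations
        df["necrosis_time"] = self.necrosis_times
        df["lineage"] = self.lineages
        if iteration is not None:
            df.insert(0, "iteration", iteration)
        return df

    @classmethod
    def from_dataframe(cls, df) -> "CellPopulation":
        axes = [a for a in "xyz" if a in df.columns]
        pop = cls(dim=len(axes))
        n = len(df)
        if n == 0:
            return pop
        states = np.array([int(CellState[s.upper()]) for s in df["state"]], dtype=np.int8)
        nt = df["necrosis_time"].to_numpy(float) if "necrosis_time" in df else np.full(n, np.nan)
        pop.add(df[axes].to_numpy(float), states, df["health"].to_numpy(float),
                df.get("generation", np.zeros(n)).to_numpy(np.int32) if hasattr(df.get("generation", None), "to_numpy") else 0,
                df.get("mutations", np.zeros(n)).to_numpy(np.int32) if hasattr(df.get("mutations", None), "to_numpy") else 0,
                df["radius"].to_numpy(float), nt,
                df["lineage"].to_numpy(np.int32) if "lineage" in df else 0)
        return pop


@dataclass
class StemCell:
    """Roaming cancer stem cell: seeds a fresh cancer cell periodically."""

    position: np.ndarray
    spawn_period: int = 70
    last_spawn: int = 0
    step_length: float = 2 * DEFAULT_RADIUS  # one cell diameter per iteration

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.spawn_period <= 0:
            raise InvalidParameterError("spawn period must be positive")


@dataclass(frozen=True)
class MitosisParams:
    """Stochastic mitosis parameters.

    r is the base per-iteration mitosis probability of a normal tissue cell;
    sigma the Gaussian noise scale of the probability; the Hayflick limit
    caps lineage depth; each daughter independently gains a mutation with
    ``mutation_increment_prob``.
    """

    r: float = 0.0315
    sigma: float = 0.01
    hayflick_limit: int = 60
    mutation_increment_prob: float = 0.05
    require_target: bool = True  # eligibility gate at h >= H_P/H_Q

    def __post_init__(self):
        if not 0 < self.r < 1:
            raise InvalidParameterError("base mitosis probability must lie in (0, 1)")
        if self.sigma < 0 or self.hayflick_limit <= 0:
            raise InvalidParameterError("sigma >= 0 and positive Hayflick limit required")
        if not 0 <= self.mutation_increment_prob <= 1:
            raise InvalidParameterError("mutation_increment_prob must be a probability")


def mitosis_mean(r: float, mu, c_gf, c_gi):
    """Mean mitosis probability M = r (1 + mu)(1 + C_GF - C_GI), floored at 0."""
    if np.any(np.asarray(c_gf) < 0) or np.any(np.asarray(c_gi) < 0):
        raise InvalidParameterError("signal concentrations must be >= 0")
    m = r * (1.0 + np.asarray(mu, dtype=float)) * (1.0 + np.asarray(c_gf) - np.asarray(c_gi))
    out = np.maximum(m, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def mitosis_probability(h: float, m: float, generation: int, sigma: float, rng,
                        hayflick_limit: int = 60) -> float:
    """Per-iteration division probability; exactly zero beyond the Hayflick limit."""
    if generation >= hayflick_limit:
        return 0.0
    eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
    return float(np.clip((h - 1.0) * m + eps, 0.0, 1.0))


def attempt_mitosis(cell: Cell, c_gf: float, c_gi: float, params: MitosisParams,
                    rng, hs: HealthState | None = None):
    """Try to divide one proliferating cell.

    Returns None, or a (daughter, daughter) pair replacing the mother: same
    position, health equally divided, generation incremented, mutations
    incremented independently with ``mutation_increment_prob``.
    """
    hs = hs or HealthState()
    if cell.state != CellState.PROLIFERATING:
        return None
    if params.require_target and cell.health < hs.mitosis_target:
        return None
    m = mitosis_mean(params.r, cell.mutations, c_gf, c_gi)
    p = mitosis_probability(cell.health, m, cell.generation, params.sigma, rng,
                            params.hayflick_limit)
    if rng.random() >= p:
        return None
    daughters = []
    for _ in range(2):
        extra = 1 if rng.random() < params.mutation_increment_prob else 0
        daughters.append(replace(
            cell, id=-1, position=cell.position.copy(), health=cell.health / 2.0,
            generation=cell.generation + 1, mutations=cell.mutations + extra,
            state=CellState.PROLIFERATING))
    return tuple(daughters)


def mitosis_step(pop: CellPopulation, c_gf: np.ndarray, c_gi: np.ndarray,
                 params: MitosisParams, rng, hs: HealthState | None = None,
                 allowed: np.ndarray | None = None) -> int:
    """Vectorized mitosis sweep over the whole population (engine path).

    Mothers that divide are converted in place into the first daughter and a
    second daughter row is appended; returns the number of divisions.
    Same rules as :func:`attempt_mitosis`, applied in array order.
    ``allowed`` optionally masks out cells mechanically blocked from dividing
    (contact inhibition at full packing).
    """
    hs = hs or HealthState()
    eligible = pop.states == int(CellState.PROLIFERATING)
    if params.require_target:
        eligible &= pop.health >= hs.mitosis_target
    eligible &= pop.generations < params.hayflick_limit
    if allowed is not None:
        eligible &= allowed
    n_el = int(eligible.sum())
    if n_el == 0:
        return 0
    m = mitosis_mean(params.r, pop.mutations[eligible], c_gf[eligible], c_gi[eligible])
    eps = rng.normal(0.0, params.sigma, size=n_el) if params.sigma > 0 else 0.0
    p = np.clip((pop.health[eligible] - 1.0) * m + eps, 0.0, 1.0)
    divide = rng.random(n_el) < p
    idx = np.flatnonzero(eligible)[divide]
    if len(idx) == 0:
        return 0
    half = pop.health[idx] / 2.0
    gen = pop.generations[idx] + 1
    mut_extra = rng.random((len(idx), 2)) < params.mutation_increment_prob
    # mother row becomes daughter 1
    pop.health[idx] = half
    pop.generations[idx] = gen
    base_mut = pop.mutations[idx].copy()
    pop.mutations[idx] = base_mut + mut_extra[:, 0]
    pop.ids[idx] = np.arange(pop._next_id, pop._next_id + len(idx))
    pop._next_id += len(idx)
    # daughter 2 appended at the same position, same lineage
    pop.add(pop.positions[idx].copy(), int(CellState.PROLIFERATING), half,
            gen, base_mut + mut_extra[:, 1], pop.radii[idx],
            lineages=pop.lineages[idx])
    return len(idx)


def stem_cell_step(stem: StemCell, iteration: int, rng, grid: DomainGrid):
    """Advance the stem cell one iteration.

    One uniform-direction random-walk step of one cell diameter, radially
    reflected at the domain boundary; emits one fresh proliferating cell
    (h=1, N=0, mu=0) when ``spawn_period`` iterations have elapsed.
    Returns the spawned :class:`Cell` or None.
    """
    if not grid.contains(stem.position):
        raise OutOfDomainError("stem cell left the domain")
    direction = rng.normal(size=grid.dim)
    norm = np.linalg.norm(direction)
    if norm > 0:
        stem.position = stem.position + stem.step_length * direction / norm
    # radial reflection at the inscribed boundary (or box clamp)
    margin = stem.step_length / 2.0
    if grid.circular:
        rel = stem.position - grid.center
        dist = np.linalg.norm(rel)
        rmax = grid.radius - margin
        if dist > rmax and dist > 0:
            stem.position = grid.center + rel / dist * (2 * rmax - dist)
    stem.position = np.clip(stem.position, margin, grid.extent - margin)
    if iteration - stem.last_spawn >= stem.spawn_period:
        stem.last_spawn = iteration
        return Cell(id=-1, position=stem.position.copy(),
                    state=CellState.PROLIFERATING, health=1.0)
    return None


def dissolve_necrotic(pop: CellPopulation, iteration: int,
                      dissolution_delay: float = 100) -> np.ndarray:
    """Remove necrotic cells dead for at least ``dissolution_delay`` iterations.

    Returns the ids of the removed cells.
    """
    expired = (pop.states == int(CellState.NECROTIC)) & (
        iteration - pop.necrosis_times >= dissolution_delay)
    removed = pop.ids[expired].copy()
    if expired.any():
        pop.keep(~expired)
    return removed
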