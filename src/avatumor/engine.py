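"""Simulation engine: configuration, the iteration loop, and run outputs.

Each iteration of length dt (default one hour) executes, in order:

1. assemble per-cell source/sink terms on the grid,
2. advance all five concentration fields (backward Euler; nutrient uptake
   treated as an implicit linear sink, production as an explicit source),
3. per-cell realized uptake, ATP yield and health update,
4. state classification (necrosis irreversible),
5. mitosis attempts (health gate + Bernoulli draw),
6. the stem-cell random walk and periodic seeding,
7. dissolution of long-dead necrotic cells,
8. mechanics: adhesion springs + chemotaxis, overdamped motion, overlap
   resolution, domain clamping,
9. bookkeeping: population ledger audit, snapshots.

Everything is driven by one seeded generator; identical configs and seeds
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import __version__
from .cells import (CellPopulation, MitosisParams, StemCell, dissolve_necrotic,
                    mitosis_step, stem_cell_step)
from .errors import ConfigurationError, InvalidParameterError
from .fields import (DomainGrid, SpeciesId, deposit_sources, initialize_fields,
                     interpolate, interpolate_gradient, uptake_coefficients)
from .mechanics import (ChemotaxisWeights, SpringConstants, adhesion_forces,
                        integrate_motion, neighbor_pairs, resolve_overlaps)
from .metabolism import (AtpStoichiometry, CellState, HealthState,
                         MetabolicRateTable, atp_total_vector)
from .morphology import classify_regions
from .physiology import BoundaryConditions
from .population import PopulationSeries

log = logging.getLogger("avatumor.engine")

__all__ = ["SimulationConfig", "SimulationResult", "run_simulation"]


@dataclass
class SimulationConfig:
    """Flat, fully defaulted simulation configuration.

    Scale defaults target desk-size runs: a 2-D 100x100 grid over a 0.2 cm
    domain (one node per 20 um cell diameter), 300 one-hour iterations.
    """

    dim: int = 2
    domain_size: float = 0.2            # cm per axis
    grid_nodes: int = 100               # nodes per axis
    dt: float = 1.0                     # hours per iteration
    iterations: int = 300
    snapshot_interval: int = 10
    seed: int = 0
    out_dir: str | None = None
    max_cells: int = 20000              # safety cap; run stops early if reached

    # nutrient/field coupling
    boundary_oxygen: float = 0.00053    # model-mM
    boundary_glucose: float = 0.005
    uptake_gain: float = 5e-4           # dimensionless cell-to-field coupling
    signal_gain: float = 2e-3           # growth factor / inhibitor coupling

    # cells
    cell_radius: float = 1e-3           # cm
    base_mitosis_probability: float = 0.0315
    mitosis_sigma: float = 0.01
    hayflick_limit: int = 60
    mutation_increment_prob: float = 0.05
    require_mitosis_target: bool = True
    dissolution_delay: int = 100
    stem_cell_enabled: bool = True
    n_stem_cells: int = 3
    stem_spawn_period: int = 70

    # mechanics
    spring_k_pp: float = 1.0
    spring_k_pq: float = 0.5
    spring_k_qq: float = 0.25
    neighbor_cutoff_factor: float = 1.2
    chemotaxis_alpha: float = 1.0
    chemotaxis_beta: float = 1.0
    chemotaxis_gamma: float = 0.5
    contact_inhibition: bool = True
    max_neighbors: int | None = None    # crowding gate; default 6 (2-D) / 12 (3-D)
    mobility: float = 0.2               # cm per force unit per hour
    chemotaxis_step_fraction: float = 0.25  # max taxis displacement, radii/iteration
    overlap_tolerance: float = 0.01     # fraction of radius
    overlap_max_iter: int = 25

    def __post_init__(self):
        if self.dim not in (2, 3):
            raise ConfigurationError("dim must be 2 or 3")
        if min(self.domain_size, self.dt) <= 0 or self.iterations < 0:
            raise ConfigurationError("domain size, dt and iterations must be positive")
        if self.grid_nodes < 10:
            raise ConfigurationError("grid_nodes must be at least 10")
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def build_grid(self) -> DomainGrid:
        return DomainGrid(extent=self.domain_size, nodes=self.grid_nodes,
                          dim=self.dim, circular=True)

    def boundary_conditions(self) -> BoundaryConditions:
        return BoundaryConditions(oxygen=self.boundary_oxygen,
                                  glucose=self.boundary_glucose)

    def mitosis_params(self) -> MitosisParams:
        return MitosisParams(r=self.base_mitosis_probability, sigma=self.mitosis_sigma,
                             hayflick_limit=self.hayflick_limit,
                             mutation_increment_prob=self.mutation_increment_prob,
                             require_target=self.require_mitosis_target)

    def springs(self) -> SpringConstants:
        return SpringConstants(self.spring_k_pp, self.spring_k_pq, self.spring_k_qq,
                               self.neighbor_cutoff_factor)

    def chemotaxis(self) -> ChemotaxisWeights:
        return ChemotaxisWeights(self.chemotaxis_alpha, self.chemotaxis_beta,
                                 self.chemotaxis_gamma)


@dataclass
class SimulationResult:
    """In-memory run outputs."""

    config: SimulationConfig
    series: PopulationSeries
    ledger: pd.DataFrame
    snapshots: dict                      # iteration -> cells DataFrame
    population: CellPopulation           # final state
    stems: list
    manifest: dict
    events: dict                         # first-occurrence iteration markers

    def snapshot_population(self, iteration: int) -> CellPopulation:
        return CellPopulation.from_dataframe(self.snapshots[iteration])


class _FieldIntegrator:
    """Backward-Euler solvers: cached factorizations for fixed operators,
    fresh factorizations for the nutrient fields whose uptake sink moves
    with the cells."""

    def __init__(self, grid: DomainGrid, dt: float):
        self.grid = grid
        self.dt = dt
        self.interior = grid.interior.ravel()
        self.lap = grid.laplacian()
        self.eye = sp.identity(grid.n_nodes, format="csr")
        self._cached = {}

    def _operator(self, diffusion: float, uptake=None):
        a = self.eye - self.dt * diffusion * self.lap
        if uptake is not None:
            k = np.asarray(uptake, dtype=float).ravel()
            a = a + sp.diags(np.where(self.interior, self.dt * k, 0.0))
        return a.tocsc()

    def step(self, f, source=None, uptake=None):
        rhs = f.values.ravel().copy()
        if source is not None:
            rhs += self.dt * np.asarray(source, dtype=float).ravel() * self.interior
        rhs[~self.interior] = f.boundary_value
        if uptake is None:
            lu = self._cached.get(f.species)
            if lu is None:
                lu = splu(self._operator(f.diffusion_constant))
                self._cached[f.species] = lu
            values = lu.solve(rhs)
        else:
            a = self._operator(f.diffusion_constant, uptake)
            values = splu(a).solve(rhs)
        values = values.reshape(self.grid.shape)
        neg = values < 0
        if neg.any():
            f.clamped_mass += float(-values[neg].sum()) * self.grid.node_volume
            values[neg] = 0.0
        f.values = values
        f.impose_boundary()


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the full multiscale loop; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    grid = config.build_grid()
    bc = config.boundary_conditions()
    fields = initialize_fields(grid, bc)
    rates = MetabolicRateTable()
    stoich = AtpStoichiometry()
    hs = HealthState()
    mp = config.mitosis_params()
    springs = config.springs()
    chemo = config.chemotaxis()
    integ = _FieldIntegrator(grid, config.dt)

    pop = CellPopulation(dim=config.dim)
    pop.add(grid.center.copy(), int(CellState.PROLIFERATING), 1.0,
            radii=config.cell_radius)
    stems = []
    if config.stem_cell_enabled:
        for _ in range(config.n_stem_cells):
            stem_pos = _random_point_in_domain(grid, rng)
            stems.append(StemCell(position=stem_pos,
                                  spawn_period=config.stem_spawn_period,
                                  step_length=2 * config.cell_radius))

    # chemotaxis normalization: a boundary-scale gradient (C_b over the domain
    # radius) displaces a cell by at most one radius per iteration
    m_scale = (chemo.alpha * bc.oxygen + chemo.beta * bc.glucose) / grid.radius
    chemo_step = config.cell_radius / m_scale if m_scale > 0 else 0.0

    series_rows = []
    ledger_rows = []
    snapshots = {}
    events = {"first_quiescent": None, "first_necrotic": None,
              "first_satellite_spawn": None, "first_satellite_tumor": None}
    n_spawned = 0
    truncated = False

    def record(iteration):
        counts = pop.counts()
        series_rows.append({
            "iteration": iteration,
            "proliferating": counts[CellState.PROLIFERATING],
            "quiescent": counts[CellState.QUIESCENT],
            "necrotic": counts[CellState.NECROTIC],
        })

    def snapshot(iteration):
        snapshots[iteration] = pop.to_dataframe(iteration)

    record(0)
    snapshot(0)

    for it in range(1, config.iterations + 1):
        n_before = len(pop)
        try:
            # (1)-(2) fields
            living = pop.living_mask
            sources = deposit_sources(pop, grid, rates, fields=None,
                                      gain=config.uptake_gain,
                                      signal_gain=config.signal_gain)
            uptake = uptake_coefficients(pop, grid, rates, bc, config.uptake_gain)
            integ.step(fields[SpeciesId.OXYGEN], uptake=uptake[SpeciesId.OXYGEN])
            integ.step(fields[SpeciesId.GLUCOSE], uptake=uptake[SpeciesId.GLUCOSE])
            integ.step(fields[SpeciesId.WASTE], source=sources[SpeciesId.WASTE])
            integ.step(fields[SpeciesId.GROWTH_FACTOR],
                       source=sources[SpeciesId.GROWTH_FACTOR])
            integ.step(fields[SpeciesId.GROWTH_INHIBITOR],
                       source=sources[SpeciesId.GROWTH_INHIBITOR])

            # (3) uptake, ATP, health
            if living.any():
                lpos = pop.positions[living]
                f_o = np.clip(interpolate(grid, fields[SpeciesId.OXYGEN].values, lpos)
                              / bc.oxygen, 0.0, 1.0)
                f_g = np.clip(interpolate(grid, fields[SpeciesId.GLUCOSE].values, lpos)
                              / bc.glucose, 0.0, 1.0)
                demand_o = rates.demand_vector(pop.states[living], "oxygen")
                demand_g = rates.demand_vector(pop.states[living], "glucose")
                atp = atp_total_vector(demand_o * f_o, demand_g * f_g, stoich)
                pop.health[living] = (pop.health[living] + atp / hs.h_quiescent
                                      - hs.decay * config.dt)

            # (4) classification
            prev_states = pop.states.copy()
            new_states = np.where(
                pop.health > hs.proliferation_threshold, int(CellState.PROLIFERATING),
                np.where(pop.health < hs.necrosis_threshold,
                         int(CellState.NECROTIC), int(CellState.QUIESCENT)))
            new_states = np.where(prev_states == int(CellState.NECROTIC),
                                  int(CellState.NECROTIC), new_states).astype(np.int8)
            newly_necrotic = (new_states == int(CellState.NECROTIC)) & (
                prev_states != int(CellState.NECROTIC))
            pop.necrosis_times[newly_necrotic] = it
            pop.states = new_states
            if events["first_quiescent"] is None and np.any(
                    pop.states == int(CellState.QUIESCENT)):
                events["first_quiescent"] = it
            if events["first_necrotic"] is None and newly_necrotic.any():
                events["first_necrotic"] = it

            # (5) mitosis, blocked for cells with no room to divide
            gf = interpolate(grid, fields[SpeciesId.GROWTH_FACTOR].values, pop.positions)
            gi = interpolate(grid, fields[SpeciesId.GROWTH_INHIBITOR].values, pop.positions)
            allowed = None
            if config.contact_inhibition and len(pop) > 1:
                cap = config.max_neighbors or (6 if config.dim == 2 else 12)
                i, j, d = neighbor_pairs(pop.positions, 1.05 * pop.radii)
                degree = np.zeros(len(pop), dtype=int)
                np.add.at(degree, i, 1)
                np.add.at(degree, j, 1)
                allowed = degree < cap
                # no room while still compressed: block cells overlapping
                # a neighbor by more than 10% of the touching distance
                squeezed = d < 0.9 * (pop.radii[i] + pop.radii[j])
                if squeezed.any():
                    allowed[i[squeezed]] = False
                    allowed[j[squeezed]] = False
            divisions = mitosis_step(pop, np.atleast_1d(gf), np.atleast_1d(gi), mp,
                                     rng, hs, allowed=allowed)

            # (6) stem cells
            spawns = 0
            for stem in stems:
                newborn = stem_cell_step(stem, it, rng, grid)
                if newborn is not None:
                    n_spawned += 1
                    pop.add(newborn.position, int(newborn.state), newborn.health,
                            radii=config.cell_radius, lineages=n_spawned)
                    spawns += 1
                    if events["first_satellite_spawn"] is None:
                        events["first_satellite_spawn"] = it
            if events["first_satellite_tumor"] is None and n_spawned:
                stem_living = int(np.sum((pop.lineages > 0) & pop.living_mask))
                if stem_living >= 5:
                    events["first_satellite_tumor"] = it

            # (7) dissolution
            dissolved = len(dissolve_necrotic(pop, it, config.dissolution_delay))

            # (8) mechanics
            if len(pop) > 0:
                forces = adhesion_forces(pop.positions, pop.radii, pop.states, springs)
                new_pos = integrate_motion(pop.positions, forces, config.dt,
                                           config.mobility,
                                           max_step=config.cell_radius)
                prolif = pop.states == int(CellState.PROLIFERATING)
                if prolif.any() and chemo_step > 0:
                    go = interpolate_gradient(grid, fields[SpeciesId.OXYGEN].values,
                                              pop.positions[prolif])
                    gg = interpolate_gradient(grid, fields[SpeciesId.GLUCOSE].values,
                                              pop.positions[prolif])
                    gw = interpolate_gradient(grid, fields[SpeciesId.WASTE].values,
                                              pop.positions[prolif])
                    m = chemo.alpha * go + chemo.beta * gg - chemo.gamma * gw
                    disp = chemo_step * m
                    cap = config.chemotaxis_step_fraction * config.cell_radius
                    norms = np.linalg.norm(disp, axis=1)
                    over = norms > cap
                    if over.any():
                        disp[over] *= (cap / norms[over])[:, None]
                    new_pos[prolif] += disp
                new_pos, _ = resolve_overlaps(new_pos, pop.radii, rng=rng, grid=grid,
                                              tol=config.overlap_tolerance,
                                              max_iter=config.overlap_max_iter)
                pop.positions = new_pos

            # (9) bookkeeping: exact ledger audit
            expected = n_before + divisions + spawns - dissolved
            if len(pop) != expected:
                raise RuntimeError(
                    f"population ledger mismatch: {len(pop)} != {expected}")
            ledger_rows.append({"iteration": it, "n_cells": len(pop),
                                "divisions": divisions, "spawns": spawns,
                                "dissolved": dissolved})
            record(it)
            if it % config.snapshot_interval == 0 or it == config.iterations:
                snapshot(it)
            if len(pop) > config.max_cells:
                log.warning("max_cells reached at iteration %d; stopping early", it)
                truncated = True
                snapshot(it)
                break
        except Exception as exc:
            _dump_failure_state(config, pop, it, exc)
            raise

    series = PopulationSeries.from_records(series_rows)
    ledger = pd.DataFrame(ledger_rows, columns=["iteration", "n_cells", "divisions",
                                                "spawns", "dissolved"])
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "code_version": __version__,
        "config": config.to_dict(),
        "iterations_run": int(series.iterations[-1]),
        "truncated": truncated,
        "events": events,
    }
    result = SimulationResult(config=config, series=series, ledger=ledger,
                              snapshots=snapshots, population=pop, stems=stems,
                              manifest=manifest, events=events)
    if config.out_dir:
        _write_outputs(result)
    return result


def _random_point_in_domain(grid: DomainGrid, rng) -> np.ndarray:
    """Uniform random point inside the domain mask (rejection sampling)."""
    for _ in range(10000):
        p = rng.uniform(0, 1, size=grid.dim) * grid.extent
        if grid.contains(p):
            return p
    return grid.center.copy()


def _dump_failure_state(config, pop, iteration, exc):
    if not config.out_dir:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        pop.to_dataframe(iteration).to_csv(out / f"failure_state_t{iteration}.csv",
                                           index=False)
        (out / "failure.json").write_text(json.dumps(
            {"iteration": iteration, "error": repr(exc)}, indent=2))
    except Exception:  # best effort only
        log.exception("could not dump failure state")


def _write_outputs(result: SimulationResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.series.to_csv(out / "population_series.csv")
    result.ledger.to_csv(out / "ledger.csv", index=False)
    for it, df in result.snapshots.items():
        df.to_csv(out / f"cells_t{it}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    if len(result.population) > 0:
        report = classify_regions(result.population)
        (out / "region_report.json").write_text(json.dumps(report.to_dict(), indent=2))
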