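"""Diffusion fields: schemes, deposition, interpolation, conservation."""

import numpy as np
import pytest

from avatumor.cells import CellPopulation
from avatumor.errors import OutOfDomainError, StepSizeError
from avatumor.fields import (DEFAULT_DIFFUSION, DomainGrid, SpeciesField,
                             SpeciesId, deposit_sources, diffusion_step,
                             implicit_step, initialize_fields, interpolate,
                             sample_concentration, sample_gradient, stable_dt,
                             uptake_coefficients)
from avatumor.metabolism import CellState
from avatumor.physiology import BoundaryConditions


def make_field(grid, value=1.0, d=1e-3, boundary=1.0, species=SpeciesId.OXYGEN):
    return SpeciesField(species, grid, np.full(grid.shape, float(value)), d, boundary)


def jacobi_steady_state(grid, source, d, boundary, sweeps=200000, tol=1e-12):
    """Independent relaxation oracle for -D lap(C) = Q with Dirichlet values."""
    c = np.full(grid.shape, boundary)
    h2 = grid.spacing ** 2
    denom = 2.0 * np.sum(1.0 / h2)
    for _ in range(sweeps):
        nbr = sum(
            (np.roll(c, s, axis=ax)) / h2[ax]
            for ax in range(grid.dim) for s in (1, -1))
        new = (nbr + source / d) / denom
        new[grid.boundary] = boundary
        if np.max(np.abs(new - c)) < tol:
            return new
        c = new
    return c


class TestSpeciesAndGrid:
    def test_five_species_stable_order(self):
        assert [s.key for s in SpeciesId] == [
            "oxygen", "glucose", "waste", "growth_factor", "growth_inhibitor"]

    def test_interior_and_boundary_partition(self, small_grid):
        assert (small_grid.interior ^ small_grid.boundary).all()
        assert small_grid.boundary.any() and small_grid.interior.any()

    def test_circular_mask_excludes_corners(self, small_grid):
        assert small_grid.boundary[0, 0]
        assert small_grid.interior[10, 10]

    def test_contains(self, small_grid):
        assert small_grid.contains(small_grid.center)
        assert not small_grid.contains(np.array([0.0001, 0.0001]))  # corner


class TestInitializeFields:
    def test_default_boundary_values(self, small_grid):
        fields = initialize_fields(small_grid)
        assert np.all(fields[SpeciesId.OXYGEN].values == 0.00053)
        assert np.all(fields[SpeciesId.WASTE].values == 0.0)
        assert fields[SpeciesId.GLUCOSE].diffusion_constant == 1.52e-3

    def test_initial_override(self, small_grid):
        bc = BoundaryConditions(initial={"glucose": 0.001})
        fields = initialize_fields(small_grid, bc)
        interior = small_grid.interior
        assert np.all(fields[SpeciesId.GLUCOSE].values[interior] == 0.001)
        assert np.all(fields[SpeciesId.GLUCOSE].values[~interior] == 0.005)


class TestDiffusionStep:
    def test_uniform_steady_state(self, small_grid):
        f = make_field(small_grid, value=0.7, boundary=0.7)
        out = diffusion_step(f, None, stable_dt(small_grid, f.diffusion_constant))
        assert np.allclose(out.values, 0.7, atol=1e-15)

    def test_zero_diffusion_zero_source(self, small_grid, rng):
        values = rng.uniform(0.1, 1, small_grid.shape)
        f = SpeciesField(SpeciesId.WASTE, small_grid, values.copy(), 0.0, 0.0)
        f.impose_boundary()
        before = f.values.copy()
        out = diffusion_step(f, None, 1.0)
        assert np.array_equal(out.values, before)

    def test_stability_contract_enforced(self, small_grid):
        f = make_field(small_grid, d=DEFAULT_DIFFUSION[SpeciesId.OXYGEN])
        with pytest.raises(StepSizeError):
            diffusion_step(f, None, 1.0, subcycle=False)

    def test_subcycling_matches_many_small_steps(self, small_grid):
        f = make_field(small_grid, value=0.5, boundary=1.0, d=1e-3)
        limit = stable_dt(small_grid, 1e-3)
        coarse = diffusion_step(f, None, 4 * limit, subcycle=True)
        fine = f
        for _ in range(4):
            fine = diffusion_step(fine, None, limit)
        assert np.allclose(coarse.values, fine.values, atol=1e-12)

    def test_point_sink_steady_state_matches_jacobi_oracle(self, small_grid):
        d = 1e-3
        source = np.zeros(small_grid.shape)
        source[10, 10] = -5e-3
        oracle = jacobi_steady_state(small_grid, source, d, boundary=1.0)
        f = make_field(small_grid, value=1.0, boundary=1.0, d=d)
        dt = stable_dt(small_grid, d)
        for _ in range(6000):
            f = diffusion_step(f, source, dt)
        assert np.max(np.abs(f.values - oracle)) < 1e-8

    def test_linearity_superposition(self, box_grid, rng):
        d = 5e-4
        dt = stable_dt(box_grid, d)
        v1 = rng.uniform(1, 2, box_grid.shape)
        v2 = rng.uniform(1, 2, box_grid.shape)
        s1 = rng.uniform(0, 1e-2, box_grid.shape)
        s2 = rng.uniform(0, 1e-2, box_grid.shape)

        def step(v, s, bval):
            f = SpeciesField(SpeciesId.WASTE, box_grid, v.copy(), d, bval)
            return diffusion_step(f, s, dt, clamp=False).values

        combined = step(v1 + v2, s1 + s2, 2.0)
        separate = step(v1, s1, 1.0) + step(v2, s2, 1.0)
        assert np.allclose(combined, separate, atol=1e-12)

    def test_interior_mass_change_equals_boundary_flux(self, box_grid):
        # discrete conservation audit: with zero sources, the interior mass
        # change in one step equals the net flux through boundary faces,
        # computed independently from the pre-step field
        d = 1e-3
        dt = stable_dt(box_grid, d)
        values = np.full(box_grid.shape, 0.5)
        f = SpeciesField(SpeciesId.WASTE, box_grid, values, d, 1.0)
        f.impose_boundary()
        pre = f.values.copy()
        out = diffusion_step(f, None, dt, clamp=False)
        vol = box_grid.node_volume
        dmass = np.sum((out.values - pre)[box_grid.interior]) * vol
        flux = 0.0
        h = box_grid.spacing
        interior = box_grid.interior
        for ax in range(2):
            for shift in (1, -1):
                nbr = np.roll(pre, shift, axis=ax)
                nbr_is_boundary = np.roll(box_grid.boundary, shift, axis=ax)
                face = interior & nbr_is_boundary
                flux += np.sum((nbr - pre)[face]) / h[ax] ** 2 * vol
        assert dmass == pytest.approx(d * dt * flux, rel=1e-10)

    def test_long_integration_relaxes_to_boundary_value(self, small_grid):
        f = make_field(small_grid, value=0.1, boundary=1.0, d=1e-3)
        dt = stable_dt(small_grid, 1e-3)
        for _ in range(4000):
            f = diffusion_step(f, None, dt)
        assert np.max(np.abs(f.values - 1.0)) < 1e-6

    def test_negative_clamp_logged(self, small_grid):
        source = np.full(small_grid.shape, -10.0)
        f = make_field(small_grid, value=1e-6, boundary=1e-6, d=1e-3)
        out = diffusion_step(f, source, stable_dt(small_grid, 1e-3))
        assert out.clamped_mass > 0
        assert np.all(out.values >= 0)


class TestImplicitStep:
    def test_agrees_with_explicit_at_small_dt(self, box_grid):
        # schemes share the spatial operator; for a field smooth up to the
        # boundary their one-step difference is the O(dt^2) truncation term
        d = 1e-3
        coords = box_grid.node_coordinates()
        values = 1.0 + 0.5 * np.sin(np.pi * coords[0] / 0.02) * np.sin(
            np.pi * coords[1] / 0.02)
        f = SpeciesField(SpeciesId.WASTE, box_grid, values, d, 1.0)
        f.impose_boundary()
        dt = stable_dt(box_grid, d) / 20
        ex = diffusion_step(f, None, dt)
        im = implicit_step(f, None, dt)
        change = np.max(np.abs(ex.values - values))
        assert np.max(np.abs(ex.values - im.values)) < 0.01 * change

    def test_stiff_sink_keeps_positivity(self, small_grid):
        f = make_field(small_grid, value=1.0, boundary=1.0, d=1e-3)
        uptake = np.full(small_grid.shape, 1e4)
        out = implicit_step(f, None, 1.0, uptake=uptake)
        assert np.all(out.values >= 0)
        assert out.values[10, 10] < 1e-2  # nearly fully drawn down


class TestDeposition:
    def make_pop(self, grid, positions, states):
        pop = CellPopulation(dim=grid.dim)
        pop.add(positions, states, 1.0)
        return pop

    def test_no_cells_all_zero(self, small_grid):
        pop = CellPopulation(dim=2)
        sources = deposit_sources(pop, small_grid)
        assert all(np.all(s == 0) for s in sources.values())

    def test_necrotic_cell_only_produces_inhibitor(self, small_grid):
        pop = CellPopulation(dim=2)
        pop.add(small_grid.center, int(CellState.NECROTIC), 0.2, necrosis_times=0.0)
        sources = deposit_sources(pop, small_grid, gain=1.0)
        for sid in (SpeciesId.OXYGEN, SpeciesId.GLUCOSE, SpeciesId.WASTE,
                    SpeciesId.GROWTH_FACTOR):
            assert np.all(sources[sid] == 0)
        inhib = sources[SpeciesId.GROWTH_INHIBITOR]
        assert inhib.sum() > 0

    def test_proliferating_totals_match_table(self, small_grid):
        # a fully supplied proliferating cell deposits its table rates scaled
        # by gain and its volume fraction, conserved over overlapped nodes
        pop = self.make_pop(small_grid, small_grid.center, int(CellState.PROLIFERATING))
        gain = 0.5
        sources = deposit_sources(pop, small_grid, gain=gain)
        cell_vol = np.pi * 1e-6
        expected = {SpeciesId.OXYGEN: -108.0, SpeciesId.GLUCOSE: -162.0,
                    SpeciesId.WASTE: 240.0}
        for sid, rate in expected.items():
            total = sources[sid].sum() * small_grid.node_volume
            assert total == pytest.approx(rate * gain * cell_vol, rel=1e-9)

    def test_availability_scaling_halves_consumption(self, small_grid):
        pop = self.make_pop(small_grid, small_grid.center, int(CellState.PROLIFERATING))
        fields = initialize_fields(small_grid)
        fields[SpeciesId.OXYGEN].values *= 0.5  # half the boundary level
        full = deposit_sources(pop, small_grid, gain=1.0)
        scaled = deposit_sources(pop, small_grid, fields=fields, gain=1.0)
        assert scaled[SpeciesId.OXYGEN].sum() == pytest.approx(
            0.5 * full[SpeciesId.OXYGEN].sum(), rel=1e-9)

    def test_cell_outside_domain_rejected(self, small_grid):
        pop = self.make_pop(small_grid, np.array([0.0001, 0.0001]),
                            int(CellState.PROLIFERATING))
        with pytest.raises(OutOfDomainError):
            deposit_sources(pop, small_grid)

    def test_uptake_coefficients_scale_with_demand(self, small_grid):
        pop = self.make_pop(small_grid, small_grid.center, int(CellState.PROLIFERATING))
        k = uptake_coefficients(pop, small_grid, gain=1.0)
        bc = BoundaryConditions()
        cell_vol = np.pi * 1e-6
        assert k[SpeciesId.OXYGEN].sum() * small_grid.node_volume == pytest.approx(
            108.0 * cell_vol / bc.oxygen, rel=1e-9)


class TestSampling:
    def test_uniform_field_zero_gradient(self, small_grid):
        f = make_field(small_grid, value=0.3)
        g = sample_gradient(f, small_grid.center + 1e-4)
        assert np.allclose(g, 0.0)

    def test_linear_ramp_gradient_exact(self, small_grid):
        coords = small_grid.node_coordinates()
        slope = 7.0
        f = SpeciesField(SpeciesId.WASTE, small_grid, slope * coords[0], 1e-3, 0.0)
        g = sample_gradient(f, small_grid.center + np.array([3e-4, -2e-4]))
        assert g[0] == pytest.approx(slope, rel=1e-9)
        assert g[1] == pytest.approx(0.0, abs=1e-9)

    def test_node_value_identity(self, small_grid, rng):
        values = rng.uniform(0, 1, small_grid.shape)
        f = SpeciesField(SpeciesId.WASTE, small_grid, values, 1e-3, 0.0)
        node = np.array([10, 7])
        pos = node * small_grid.spacing
        assert sample_concentration(f, pos) == pytest.approx(values[10, 7], rel=1e-12)

    def test_outside_domain_rejected(self, small_grid):
        f = make_field(small_grid)
        with pytest.raises(OutOfDomainError):
            sample_concentration(f, np.array([0.05, 0.05]))
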