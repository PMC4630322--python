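# Methods

## Model overview

`avatumor` simulates early (avascular) tumor growth as a hybrid multiscale
system. Three layers interact once per iteration (one model hour):

- **Tissue scale.** Five biochemical species — oxygen, glucose, waste,
  growth factor, growth inhibitor — diffuse through the extracellular fluid
  over a fixed domain Ω with Dirichlet far-field concentrations,
  ∂C/∂t − ∇·(D ∇C) = Q, where Q collects per-cell production/consumption.
  Diffusion constants (cm²/h): oxygen 5.94×10⁻², glucose 1.52×10⁻³, waste
  2.124×10⁻³, growth factor/inhibitor 10⁻⁶.
- **Cellular scale.** Off-lattice circular/spherical agents (diameter
  20 µm) in one of three states — proliferating, quiescent, necrotic — with
  per-state metabolic demand rates (mM/h/cm³): proliferating consumes up to
  108 oxygen and 162 glucose and produces 240 waste and 1 growth factor;
  quiescent 50/80/110, 0.5 growth factor, 1 inhibitor; necrotic only
  produces 2 inhibitor.
- **Energy scale.** Absorbed glucose splits between aerobic oxidation
  (6 O₂ + 1 glucose → 30 ATP) and anaerobic glycolysis (1 glucose → 2 ATP),
  the Warburg partition. The per-cell health level h accumulates the
  normalized ATP balance, δh = (E₁+E₂)/H_Q − D·δt, with H_Q = 393.4 the ATP
  rate of a fully fed quiescent cell and the decay D = 1/h calibrated so
  such a cell is in exact energy balance. A fully fed proliferating cell
  produces H_P = 828, hence gains (H_P/H_Q − 1) ≈ 1.105 per hour.

State rules: h > 1.5 → proliferating; h < 0.5 → necrotic (irreversible,
dissolved after a delay); otherwise quiescent. A proliferating cell becomes
*eligible* for mitosis at h ≥ H_P/H_Q ≈ 2.105 and then divides per iteration
with probability clamp((h−1)·M + ε, 0, 1), where M = r(1+μ)(1+C_GF−C_GI)
floored at 0, r = 0.0315, μ the accumulated mutation count, and
ε ~ N(0, σ²). Division halves the mother's health between two daughters at
her position; a Hayflick limit of 60 generations caps lineage depth.
Daughters are created in the proliferating state; the next iteration's
classification demotes them to quiescent if their health stays below 1.5.
(Under the alternative — classifying daughters immediately — a daughter at
h ≈ 1.05 would adopt quiescent demand, whose ATP ceiling exactly balances
decay, and could never re-proliferate; growth would halt at two cells.)

Mechanics: non-necrotic neighbor pairs attract through Hookean springs
F = −k·d with state-dependent constants (k_PP=1.0 > k_PQ=0.5 > k_QQ=0.25,
cutoff 1.2× summed radii) — the differential adhesion hypothesis in force
form. Proliferating cells also feel chemotaxis along
m = α∇C_O + β∇C_G − γ∇C_W (α=β=1, γ=0.5). Motion is overdamped
(displacement = mobility × force × dt) and incompressibility is enforced by
iterative pairwise projection of overlaps plus clamping inside Ω.

Cancer stem cells random-walk through the domain (step one cell diameter per
iteration, radially reflected at ∂Ω), exempt from metabolism, and each
seeds one fresh proliferating cell (h=1, N=0, μ=0) every 70 iterations —
the source of satellite tumors.

## Numerical choices

- **Discretization.** Regular finite differences on a rectangular grid with
  an inscribed circular/spherical Dirichlet mask; all array-edge nodes are
  also Dirichlet nodes. Cells couple to the grid with cloud-in-cell
  (multilinear) deposition and interpolation.
- **Time stepping.** The explicit FTCS scheme enforces
  dt ≤ h²/(2·dim·D) and sub-cycles otherwise; the engine instead uses
  unconditionally stable backward Euler with the nutrient uptake sink
  linearized onto the operator diagonal, −(demand/C_boundary)·C, which keeps
  concentrations non-negative even for stiff sinks (M-matrix). Factorizations
  of fixed operators are cached; nutrient operators are refactorized per
  iteration as cells move. Negative values from odd explicit sources are
  clamped to zero and the removed mass is logged.
- **Demand scaling.** The tabulated demand rates (~10² mM/h/cm³) and the
  boundary concentrations (~10⁻³ mM) differ by ~10⁵ and the source text does
  not reconcile the scales. Realized uptake is demand × clamp(C/C_b, 0, 1)
  (linear saturation), and cell demand enters the field equations through a
  single dimensionless coupling `uptake_gain`. Its default (5×10⁻⁴) was set
  once so that the glucose screening length at confluent packing is roughly
  a dozen cell diameters — the diffusion-limited regime in which layered
  spheroids (rim/quiescent/necrotic) form at desk scale. Growth factor and
  inhibitor use a separate `signal_gain` (2×10⁻³) so their concentrations
  reach the O(0.1) range where they visibly modulate M.
- **Contact inhibition.** A cell may not divide while it has ≥ 6 contacts
  (2-D; 12 in 3-D) at ~1.05× touching distance or while it overlaps any
  neighbor by more than 10 % of the touching distance. This enforces the
  incompressible-body assumption mechanically: without it, rim divisions
  outrun the projection resolver and the packing density grows without
  bound. It is configurable (`contact_inhibition`).
- **Chemotaxis normalization.** The taxis force is scaled so a
  boundary-scale gradient (C_b across the domain radius) displaces a cell by
  at most one radius per iteration, and the per-iteration taxis displacement
  is further capped at 0.25 radius so that adhesion (springs vanish beyond
  the 1.2× cutoff) can keep the tumor connected.
- **Ties and degenerate inputs.** Coincident cell centers exert no spring
  force and are separated along a seeded random direction by the overlap
  resolver; necrosis at exactly h = 0.5 does not trigger (strict
  inequality); a constant count series is rejected as a degenerate sigmoid
  fit with a diagnostic.

## Study-scale defaults and what runs show

The default configuration is deliberately desk-sized: 2-D, circular domain
of radius 0.1 cm (≈ 50 cell diameters), 100×100 grid (one node per cell
diameter), dt = 1 h, 300 iterations, three stem cells, seed-driven
reproducibility (identical seeds give byte-identical outputs). A full run
takes on the order of a minute on one CPU and plateaus at a few thousand
living cells. The canonical staging emerges in order: exponential growth of
the founder's colony; quiescent cells in the interior once local glucose
sags; necrosis deeper in; a population plateau whose living count
oscillates in a narrow band; and, with the stem cells enabled, at least one
satellite tumor from a seeded lineage. The emergent morphology shows the
four-zone structure: pure necrotic core (U_N), mixed necrotic–quiescent
annulus with agglomerations, quiescent band, and mixed
proliferating/quiescent rim out to U_T.

Two intentional departures from naive expectations are worth recording:

- The *exponential window* of a run is measured from the iteration the
  living count first reaches 12 until it first reaches 128. Below ~12 cells
  the series is single-lineage stochastics (a run can sit at N=1 for ten
  iterations before the founder's first division); beyond ~128 crowding and
  nutrient limitation begin to bend the curve.
- The *mean-field check* of the stochastic birth process (waiting times
  exponential with hazard h(N) = rN(1−N/K)) against the logistic closed
  form is performed at moderate N₀ (100 at K = 1000). At N₀ ≈ 1 the raw
  Monte-Carlo mean measurably deviates from the deterministic curve —
  trajectory-timing spread, a real demographic-noise effect, not an
  implementation error. The printed waiting-time map δt = e^h is also
  implemented behind `printed_waiting_map=True` for comparison; it is not a
  waiting-time distribution and is never used by default.

## Parameters that matter

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `boundary_oxygen` | 0.00053 | model-mM | plasma oxygen at ∂Ω (hemoglobin/Hill derivation) |
| `boundary_glucose` | 0.005 | model-mM | extracellular-fluid glucose at ∂Ω |
| `uptake_gain` | 5×10⁻⁴ | — | cell-demand → field-sink coupling (sets screening length) |
| `signal_gain` | 2×10⁻³ | — | growth factor/inhibitor coupling |
| `base_mitosis_probability` | 0.0315 | /iter | normal-tissue division probability r |
| `mitosis_sigma` | 0.01 | — | σ of the division-probability noise (unstated in the source; chosen small relative to r's effect) |
| `mutation_increment_prob` | 0.05 | /daughter | chance a daughter gains a mutation |
| `hayflick_limit` | 60 | divisions | lineage depth cap |
| `stem_spawn_period` | 70 | iterations | stem-cell seeding period |
| `n_stem_cells` | 3 | — | roaming stem cells (a single stem barely moves, so its spawns all probe one location; three express the mechanism robustly) |
| `dissolution_delay` | 100 | iterations | necrotic-body persistence before removal |
| `cell_radius` | 10 | µm | agent radius |

Units note: the source data writes concentrations as "mM/cm³" with mol/L
magnitudes; all printed numbers are carried at face value in one internal
unit ("model-mM") and the hemoglobin conversion reproduces the printed
0.0019–0.0023 range under that convention.

## What the synthetic fixtures emulate — and what they do not

`morphology.generate_fixture` builds deterministic snapshots with known
ground truth: hex-packed layered tumors (pure annuli by construction),
uniform random "gas", planted necrotic clusters in a quiescent sea, and a
two-tumor scene mirroring the stem-cell secondary-tumor scenario. These
validate the *analysis* operations (region radii recovered within one shell
width; planted cluster count recovered exactly) independently of the
simulator. They do not emulate mechanical jitter, partial-volume mixing at
annulus borders, or the irregular necrotic agglomerations real runs produce,
so passing fixture tests demonstrates correctness of the measurement
operators, not realism of grown tumors — the staged-run checks cover the
latter qualitatively.

## Known limitations

- The plateau is partly geometric: the tumor grows until its rim approaches
  the nutrient-rich boundary ring, so carrying capacity depends on domain
  size as well as boundary concentrations (doubling the nutrient boundaries
  raises the plateau, as asserted in tests).
- Quiescent cells at any sub-boundary concentration are in slight energy
  deficit (their ATP ceiling equals the decay), so the pure quiescent band
  is thin and turns over continuously; at these desk scales the mixed
  annulus dominates.
- 3-D runs are supported throughout but default tests and documented scales
  are 2-D; 3-D at comparable resolution is an order of magnitude slower.
- The fitted constants of the reference population curves are used as
  synthetic-data generator parameters for recovery tests; regenerating them
  from fresh agent runs is out of scope (they depend on an unpublished
  domain configuration at ~10⁷ cells).
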