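# Methods

This note records the model as implemented, the numerical choices, and what
the shipped desk-scale studies do and do not demonstrate.

## Cell model

### Phases and transitions

Cells occupy one of six phases.  Living: PREMITOTIC (preparing division),
POSTMITOTIC (post-division recovery), QUIESCENT.  Dead: APOPTOTIC,
EARLY_NECROTIC (oncosis), LATE_NECROTIC (post-rupture debris).  The two
necrotic stages jointly represent necrosis; keeping them separate matters
for necrotic-core microstructure, because swelling cells push their viable
neighbors outward before rupturing.

Deterministic transitions fire when the phase clock reaches the phase
duration (T_prem = 13 h to division, T_postm = 2.5 h to quiescence); the
clock is zeroed on every transition, so deterministic residence times are
exact to within one phase step.  Stochastic transitions use one uniform
draw per cell per transition per step against probability r·Δt — the
linearization of an exponential waiting time, accurate for r·Δt ≪ 1 (at the
default Δt_phase = 6 min the largest probability, saturated necrosis, is
0.017).  A calibration test verifies the realized 10-hour apoptotic dead
fraction of 10⁵ cells against 1 − e^(−rt) within binomial error.

Within one phase step the order is fixed: death tests (apoptosis, then
necrosis) → division queueing → postmitotic→quiescent → quiescent
activation → rupture → clock advance.  The ordering effect is O(Δt²); it is
fixed and documented so runs are reproducible, not because the order is
physically identified.

Oxygen enters through two piecewise-linear ramps: activation rate rises
from 0 at 5 mmHg to its 0.1176 h⁻¹ maximum at 10 mmHg; necrosis rate rises
from 0 at 5 mmHg (falling oxygen) to 0.1667 h⁻¹ at 2.5 mmHg.

### Volumes

dV_i/dt = −r_{p,i}(V_i − V_iᵖ) per component (fluid, nuclear solid,
cytoplasmic solid), integrated with explicit Euler at the phase cadence
(Δt·r ≤ 0.3 for every default rate, well inside stability).  Targets:

| phase            | V_F target | V_NS target | V_CS target |
|------------------|-----------|-------------|-------------|
| premitotic       | 0.7502·V  | 270 µm³     | 976 µm³     |
| postmitotic/quiescent | 0.7502·V | 135 µm³ | 488 µm³     |
| apoptotic        | 0         | 0           | 0           |
| early necrotic   | V (swelling) | 0        | 0           |
| late necrotic    | 0         | 0           | 0           |

The early-necrotic fluid target equals the current total volume, so the
fluid fraction rises toward 1 and the cell swells at rate r_F·(V − V_F);
rupture to LATE_NECROTIC triggers at V ≥ 2·V_std (the rupture criterion is
a modeling choice; only the existence of rupture is physically given).
Dead cells are removed when V < 0.02·V_std.  The volume relaxation sign
convention is the one that makes targets attractors; tests pin the
trajectory to the closed-form exponential with first-order error in Δt.

A note on consistency: the quiescent targets imply a standard cell volume
V_std = (135 + 488)/(1 − 0.7502) ≈ 2494 µm³ (R ≈ 8.41 µm), which is also
the seed-cell volume used by both scenario initializers.

### Division

A premitotic cell whose clock has reached T_prem splits instantly: each
daughter takes exactly half of every volume component and sits at the
parent center ± (R − R/2^{1/3})·θ with θ uniform on the sphere, so two
half-volume spheres straddle the parent center.  Daughters enter
POSTMITOTIC with zeroed clocks and inherit the parent's velocity history.

## Mechanics

Overdamped center dynamics with drag η = 1 and force constants expressed
directly in µm/min: repulsion C_ccr = 10, adhesion C_cca = 0.4, adhesion
range factor 1.25 (all configurable).  These magnitudes are inherited from
the reference center-based model family, not fitted here.  The two-cell
equilibrium separation implied by the defaults, 16.02 µm for standard
cells (≈ 5 % overlap), is verified in tests against a scalar root-find and
by relaxing the dynamical system.

Positions advance with second-order Adams–Bashforth,
x ← x + Δt/2·(3v − v_prev); the first step (and nothing else) falls back to
forward Euler because no previous velocity exists.  Newly created
daughters copy the parent's stored previous velocity.

Neighbor search: Morton keys interleave the voxel indices (bit b of i at
key bit 3b, j at 3b+1, k at 3b+2); a stable argsort replaces the GPU radix
sort of high-performance implementations — the output contract (ascending
keys, contiguous voxel ranges) is identical and is what the correctness
tests check.  Because grid construction enforces dx ≥ R_A^max
(= 1.25·2·R_std ≈ 21.03 µm for the default tables), the 27-voxel gather is
exact, and a mandatory test checks it against the all-pairs O(N²) sum to
1e−10 on random configurations.

Confinement is projection-based: centers are clamped into the domain box
with a one-cell-radius margin, and in the duct scenario additionally to
radial distance ≤ R_duct − R_cell and axially in front of the closed end.

## Oxygen transport

One diffusible substance (oxygen, mmHg) on the same isotropic lattice:

- uptake map: U_i = Σ_{living cells in voxel} (V_cell/V_voxel)·U_o,
  U_o = 10 min⁻¹; dead cells consume nothing;
- LOD diffusion–decay: three sequential implicit 1-D sweeps (x, y, z), each
  with a third of the decay rate, each a tridiagonal solve by the Thomas
  algorithm with zero-flux end rows;
- implicit supply/uptake: ρ ← (ρ + Δt·S·ρ*)/(1 + Δt(S + U));
- Dirichlet boundaries as pinned voxel sets re-imposed after every
  operator (domain faces for HDS at 38 mmHg; the one-voxel-thick duct-wall
  shell for DCIS at 7.2 mmHg, built by 6-adjacency to the lumen so it is
  topologically closed — verified by flood fill).

Transport constants (D = 10⁵ µm²/min, λ = 0.1 min⁻¹, 38 mmHg far-field)
are the standard oxygen reference values of this model family.

Every operator is unconditionally stable and non-negativity preserving,
and the zero-flux discretization conserves mass exactly with λ = 0 (the
implicit matrix has unit column sums).  The splitting is first order; with
constant coefficients and no pinning the three 1-D sweeps commute exactly,
and with pinning the sweep-order dependence is O(Δt²) (both tested).

**Solver step size.**  The splitting error grows with Δt·D/Δx² (sequential
sweeps) and Δt·U (stiff local uptake), so the solver step is kept at
Δt_diff = 0.01 min, the accuracy-validated reference value; we verified
against an independent sparse steady-state solve that coarser steps bias
the quasi-steady field by tens of percent.  Because oxygen equilibrates in
fractions of a minute while cells move and divide over hours, the
scheduler treats the field as quasi-steady: per mechanics tick it takes
`diff_substeps` solver steps (default: fully synchronous, i.e.
Δt_mech/Δt_diff of them; the desk-scale studies use 15 per 1-minute tick
after a 1000-step burn-in at t = 0).  A regression test shows the
subcycled field tracks the synchronous solution to better than 2 %.

## Scheduler

One seeded RNG stream drives every stochastic choice in a fixed order
(initialization, then per phase-step: death/activation draws, division
directions), so equal seeds give bit-identical trajectories — asserted by
test.  Cadences: mechanics every Δt_mech, phases every Δt_phase (integer
ratio enforced), diffusion substeps as above; when cadences coincide the
order is diffusion → mechanics → phases.  Runs stop early, with a final
record, if the population dies out.

Scenario initializers: HDS seeds n cells uniformly in a sphere sized for a
0.64 (random-close-packing) volume fraction, all quiescent at standard
volume with clocks drawn uniform in [0, 1/r_pro_max) to avoid artificial
division synchrony; DCIS packs a plug of seed cells against the closed end
of the duct at the same packing fraction.

## Desk-scale study conditions

The shipped studies are sized for minutes-per-run on one core:

- **HDS**: 500 seed cells, 60³ voxels of 25 µm, 72 h simulated,
  Δt_mech = 1 min, Δt_phase = 6 min, 15 diffusion substeps/tick.
- **DCIS**: duct radii 100/150/200 µm in a 1000×600×600 µm domain, 300
  seed cells, 96 h simulated, same stepping; front position is the 99th
  percentile of living-cell axial coordinates and the advance rate its
  least-squares slope in µm/day.

What they show: exponential early spheroid growth with a near-linear
radius trace; hypoxia must precede any necrosis; and the DCIS front
advance rate strictly decreases with duct radius (measured 12.8 > 9.4 >
6.6 µm/day at radii 100/150/200 µm), the inverse relationship expected
when proliferation is fed by wall-supplied oxygen.

What they do not show: a necrotic core.  Under the reference oxygen
constants a packed spheroid's center only falls below the 5 mmHg necrosis
threshold at radius ≈ 350 µm; from 500 seed cells (initial radius
≈ 78 µm, population doubling ≈ 23 h) the 72-hour window tops out near
150 µm, so necrotic-core formation and the constant-viable-rim linear
growth regime are reachable only in much longer, larger runs.  The physics
that produces them (oxygen-ramped proliferation, threshold necrosis,
swelling/rupture) is fully exercised by the unit and property tests.

## Measurement conventions

Population "radius" is the 97.5th percentile of cell-center distances from
the centroid plus the mean cell radius (robust to stragglers; maximum and
other percentiles available).  The necrotic core radius applies the same
estimator to necrotic cells about their own centroid.  All metrics are
permutation- and translation-invariant.

## Known limitations

- Single substrate; the data model holds one field (a list would be a
  small extension) and only oxygen is exercised.
- No motility forces (zero-default hook), no cell–ECM adhesion beyond the
  scalar drag, rigid duct, no angiogenesis/vasculature.
- Explicit Euler volume integration and first-order operator splitting:
  accuracy is first order in the respective steps; defaults keep the error
  terms small rather than eliminating them.
- Coincident cell centers (probability-zero but possible after aggressive
  confinement) fall back to a deterministic axis-aligned repulsion pair.
- The mechanics step bounds per-step displacement by the bounded force
  laws but is not adaptive; heavily overlapping transients (fresh
  divisions) relax over a few steps rather than within one.
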