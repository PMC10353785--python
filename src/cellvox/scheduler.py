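"""Multiscale main loop and scenario initializers.

The three physics modules run at their own cadences on a shared tick of
``dt_diff`` minutes: every tick the oxygen field is updated (uptake map,
LOD diffusion-decay, supply/uptake); every ``dt_mech`` the cells are
voxel-sorted, forces aggregated and positions advanced; every
``dt_phase`` the cells read their local oxygen and run phase, volume and
birth-death updates.  When cadences coincide, diffusion runs before
mechanics before phases.  A single seeded RNG stream drives every
stochastic choice, so equal seeds give bit-identical trajectories.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, List, Optional

import numpy as np
import pandas as pd

from . import cycle, mechanics, metrics, microenv
from .grid import Grid
from .microenv import Field
from .params import (DuctGeometry, Phase, SimulationConfig, max_interaction_distance,
                     validate_config)
from .population import CellPopulation

__all__ = [
    "SimResult",
    "run",
    "init_hds",
    "init_dcis",
    "scaled_hds_config",
    "scaled_dcis_config",
]


@dataclass
class SimResult:
    """Trajectory summary returned by :func:`run`."""

    config: SimulationConfig
    grid: Grid
    population: CellPopulation
    field: Field
    metrics: pd.DataFrame
    events: pd.DataFrame
    snapshots: List[tuple] = dc_field(default_factory=list)
    counters: dict = dc_field(default_factory=dict)
    stopped_early: bool = False


# ----------------------------------------------------------------------
# scenario initializers
# ----------------------------------------------------------------------
def _standard_state(n: int, config: SimulationConfig, rng: np.random.Generator):
    """Quiescent seed cells at standard volume with desynchronized clocks."""
    vp = config.volume
    phase = np.full(n, int(Phase.QUIESCENT))
    V_NS = np.full(n, vp.V_NS_target[Phase.QUIESCENT])
    V_CS = np.full(n, vp.V_CS_target[Phase.QUIESCENT])
    V_F = np.full(n, vp.V_F_std)
    V = V_F + V_NS + V_CS
    # uniform clock in [0, mean activation wait) avoids artificial synchrony
    clock = rng.uniform(0.0, 60.0 / config.phase.r_pro_max, size=n)
    return phase, V, V_F, V_NS, V_CS, clock


def _make_field(grid: Grid, config: SimulationConfig, mask: np.ndarray,
                value: float) -> Field:
    u = config.microenv
    rho = np.full(grid.shape, value, dtype=float)
    return Field(rho=rho, rho_star=u.rho_star, D=u.D, lam=u.lam,
                 S=0.0, U=np.zeros(grid.shape),
                 dirichlet_mask=mask, dirichlet_values=value)


def init_hds(n_cells: int, cluster_radius: float, grid: Grid,
             config: SimulationConfig, rng: np.random.Generator):
    """Hanging-drop spheroid start: a random spherical cell cluster.

    ``n_cells`` quiescent cells at standard volume are placed uniformly
    in a sphere of ``cluster_radius`` at the domain center; the oxygen
    field is uniform at the boundary value with Dirichlet domain faces
    (oxygen diffuses in from the drop boundary).
    """
    center = 0.5 * (grid.origin + grid.upper)
    u = rng.random(n_cells)
    d = rng.normal(size=(n_cells, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    pos = center + cluster_radius * u[:, None] ** (1.0 / 3.0) * d

    phase, V, V_F, V_NS, V_CS, clock = _standard_state(n_cells, config, rng)
    pop = CellPopulation(pos, phase, V, V_F, V_NS, V_CS, phase_clock=clock)

    mask = np.zeros(grid.shape, dtype=bool)
    mask[0, :, :] = mask[-1, :, :] = True
    mask[:, 0, :] = mask[:, -1, :] = True
    mask[:, :, 0] = mask[:, :, -1] = True
    field = _make_field(grid, config, mask, config.microenv.boundary_value)
    return pop, field


def duct_lumen_mask(grid: Grid, duct: DuctGeometry) -> np.ndarray:
    """Voxels whose center lies inside the duct lumen."""
    a = duct.axis_vector()
    xs = grid.voxel_centers_axis(0)
    ys = grid.voxel_centers_axis(1)
    zs = grid.voxel_centers_axis(2)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    centers = np.stack([X, Y, Z], axis=-1)
    rel = centers - duct.closed_end_position * a
    axial = rel @ a
    radial = np.linalg.norm(rel - axial[..., None] * a, axis=-1)
    return (radial < duct.radius) & (axial > 0.0) & (axial < duct.length)


def duct_wall_mask(grid: Grid, duct: DuctGeometry) -> np.ndarray:
    """One-voxel-thick shell of wall voxels enclosing the lumen.

    A voxel belongs to the wall if it is outside the lumen but
    face-adjacent (6-connectivity) to a lumen voxel, which guarantees a
    topologically closed shell: every 6-connected path from the lumen to
    the domain exterior crosses it (except through the open end, where
    the lumen meets the domain face).
    """
    lumen = duct_lumen_mask(grid, duct)
    neighbor = np.zeros_like(lumen)
    for axis in range(3):
        for shift in (1, -1):
            shifted = np.zeros_like(lumen)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift == 1:
                src[axis] = slice(0, -1)
                dst[axis] = slice(1, None)
            else:
                src[axis] = slice(1, None)
                dst[axis] = slice(0, -1)
            shifted[tuple(dst)] = lumen[tuple(src)]
            neighbor |= shifted
    return neighbor & ~lumen


def init_dcis(duct: DuctGeometry, n_seed: int, grid: Grid,
              config: SimulationConfig, rng: np.random.Generator):
    """DCIS start: a packed tumor plug at the closed end of the duct.

    Oxygen is held at the wall boundary value on the one-voxel-thick
    Dirichlet shell of wall voxels; the open end (domain face) is left
    zero-flux.  Seed cells are placed uniformly in a cylindrical plug
    whose length gives the configured packing fraction.
    """
    a = duct.axis_vector()
    vp = config.volume
    r_cell = vp.R_std
    r_max = duct.radius - r_cell

    if n_seed > 0:
        plug_len = max(n_seed * vp.V_std / (config.cluster_packing * np.pi * r_max ** 2),
                       2.0 * r_cell)
        axial = duct.closed_end_position + r_cell + rng.uniform(0.0, plug_len, n_seed)
        rr = r_max * np.sqrt(rng.random(n_seed))
        ang = rng.uniform(0.0, 2.0 * np.pi, n_seed)
        # orthonormal frame perpendicular to the duct axis
        ref = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(a, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        pos = (axial[:, None] * a[None, :]
               + rr[:, None] * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2))
        phase, V, V_F, V_NS, V_CS, clock = _standard_state(n_seed, config, rng)
        pop = CellPopulation(pos, phase, V, V_F, V_NS, V_CS, phase_clock=clock)
    else:
        pop = CellPopulation.empty()

    mask = duct_wall_mask(grid, duct)
    field = _make_field(grid, config, mask, config.microenv.boundary_value)
    return pop, field


# ----------------------------------------------------------------------
# main loop
# ----------------------------------------------------------------------
def _initialize(config: SimulationConfig, rng: np.random.Generator):
    grid = Grid(config.nx, config.ny, config.nz, config.dx,
                origin=config.origin,
                min_interaction_distance=max_interaction_distance(
                    config.volume, config.mechanics))
    if config.scenario == "dcis":
        pop, field = init_dcis(config.duct, config.n_seed, grid, config, rng)
    else:
        radius = config.cluster_radius
        if radius is None:
            radius = default_cluster_radius(config)
        pop, field = init_hds(config.n_seed, radius, grid, config, rng)
    return grid, pop, field


def default_cluster_radius(config: SimulationConfig) -> float:
    """Seed-cluster radius giving the configured packing fraction [um]."""
    return (config.n_seed * config.volume.V_std /
            (config.cluster_packing * 4.0 / 3.0 * np.pi)) ** (1.0 / 3.0)


def run(config: SimulationConfig,
        on_output: Optional[Callable] = None,
        store_snapshots: bool = False) -> SimResult:
    """Run a full simulation; return metrics series and final state.

    ``on_output(t_min, pop, field)`` is called at every output time (and
    at t = 0); with ``store_snapshots`` population/field copies are also
    kept in memory.  The run stops early (with a final record) if the
    population dies out.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))

    rng = np.random.default_rng(config.seed)
    grid, pop, field = _initialize(config, rng)
    duct = config.duct if config.scenario == "dcis" else None

    sync_substeps = round(config.dt_mech / config.dt_diff)
    substeps = sync_substeps if config.diff_substeps is None \
        else min(config.diff_substeps, sync_substeps)
    phase_every = round(config.dt_phase / config.dt_mech)
    out_every = max(round(config.output_every / config.dt_mech), 1)
    n_ticks = round(config.t_end / config.dt_mech)

    rows, event_rows, snapshots = [], [], []
    counters = {"diffusion_steps": 0, "mechanics_steps": 0, "phase_steps": 0}

    def record(t):
        counts = pop.phase_counts()
        p_oxy = (microenv.sample_concentration(pop, field, grid)
                 if pop.n else np.zeros(0))
        row = {
            "t_min": t,
            "n_total": pop.n,
            "n_premitotic": counts[0], "n_postmitotic": counts[1],
            "n_quiescent": counts[2], "n_apoptotic": counts[3],
            "n_early_necrotic": counts[4], "n_late_necrotic": counts[5],
            "radius_um": metrics.spheroid_radius(pop) if pop.n else np.nan,
            "necrotic_radius_um": metrics.necrotic_core_radius(pop) if pop.n else np.nan,
            "min_oxygen_mmHg": float(p_oxy.min()) if pop.n else np.nan,
            "mean_oxygen_mmHg": float(p_oxy.mean()) if pop.n else np.nan,
        }
        if duct is not None:
            row["front_um"] = metrics.duct_front(pop, duct)
        rows.append(row)
        if on_output is not None:
            on_output(t, pop, field)
        if store_snapshots:
            snapshots.append((t, pop.copy(), field.copy()))

    # one-off field equilibration against the initial uptake map
    if config.diff_burnin:
        field.U = microenv.compute_uptake(pop, grid, config.microenv)
        for _ in range(config.diff_burnin):
            microenv.lod_diffusion_step(field, grid, config.dt_diff)
            microenv.supply_uptake_step(field, config.dt_diff)

    record(0.0)
    stopped_early = False

    for tick in range(1, n_ticks + 1):
        t = tick * config.dt_mech

        # --- microenvironment: dt_diff solver substeps ---------------
        field.U = microenv.compute_uptake(pop, grid, config.microenv)
        for _ in range(substeps):
            microenv.lod_diffusion_step(field, grid, config.dt_diff)
            microenv.supply_uptake_step(field, config.dt_diff)
        counters["diffusion_steps"] += substeps

        # --- mechanics (every tick) ----------------------------------
        if pop.n:
            mechanics.sort_by_voxel(pop, grid)
            F = mechanics.aggregate_forces(pop, grid, config.mechanics)
            v = mechanics.velocities(F, config.mechanics)
            mechanics.update_positions(pop, v, config.dt_mech)
            mechanics.apply_confinement(pop, grid, duct)
            counters["mechanics_steps"] += 1

        # --- phase cadence -------------------------------------------
        if tick % phase_every == 0:
            p_oxy = microenv.sample_concentration(pop, field, grid)
            res = cycle.update_phases(pop, p_oxy, config.dt_phase,
                                      config.phase, config.volume, rng)
            cycle.update_volumes(pop, config.dt_phase, config.volume)
            n_removed = int(res.removal_flags.sum())
            pop = cycle.apply_birth_death(pop, res.division_indices,
                                          res.removal_flags, rng)
            counters["phase_steps"] += 1
            event_rows.append({
                "t_min": t,
                "births": len(res.division_indices),
                "apoptotic_deaths": res.n_apoptotic_deaths,
                "necrotic_deaths": res.n_necrotic_deaths,
                "activations": res.n_activations,
                "removals": n_removed,
            })
            if pop.n == 0:
                record(t)
                stopped_early = True
                break

        if tick % out_every == 0 and not stopped_early:
            record(t)

    return SimResult(config=config, grid=grid, population=pop, field=field,
                     metrics=pd.DataFrame(rows), events=pd.DataFrame(event_rows),
                     snapshots=snapshots, counters=counters,
                     stopped_early=stopped_early)


# ----------------------------------------------------------------------
# desk-scale study configurations
# ----------------------------------------------------------------------
def scaled_hds_config(seed: int = 0) -> SimulationConfig:
    """Scaled-down hanging-drop spheroid study.

    500 seed cells in a 60^3 lattice of 25 um voxels, 72 h of simulated
    growth.  The oxygen solver keeps its 0.01 min step (15 quasi-steady
    substeps per 1 min mechanics tick after a 10 min burn-in); phases
    update every 6 min.
    """
    return SimulationConfig(
        scenario="hds", seed=seed,
        dt_diff=0.01, dt_mech=1.0, dt_phase=6.0,
        t_end=72.0 * 60.0, output_every=120.0,
        diff_substeps=15, diff_burnin=1000,
        nx=60, ny=60, nz=60, dx=25.0,
        n_seed=500,
    )


def scaled_dcis_config(duct_radius: float, seed: int = 0) -> SimulationConfig:
    """Scaled-down DCIS study for one duct radius.

    A 1000 x 600 x 600 um domain with the duct along +x, closed end
    100 um from the low-x face, 7.2 mmHg Dirichlet oxygen on the duct
    wall shell, 300 seed cells packed at the closed end, 96 h of growth.
    """
    duct = DuctGeometry(axis=(1.0, 0.0, 0.0), radius=duct_radius,
                        length=1000.0, closed_end_position=-400.0)
    cfg = SimulationConfig(
        scenario="dcis", seed=seed,
        dt_diff=0.01, dt_mech=1.0, dt_phase=6.0,
        t_end=96.0 * 60.0, output_every=120.0,
        diff_substeps=15, diff_burnin=1000,
        nx=40, ny=24, nz=24, dx=25.0,
        n_seed=300, duct=duct,
    )
    cfg.microenv.boundary_value = 7.2
    cfg.microenv.rho_star = 7.2
    return cfg
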