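"""Stochastic cell-cycle phase transitions, component volume ODEs,
division and birth-death array maintenance.

Phase machinery: premitotic -> postmitotic (division) and postmitotic ->
quiescent are deterministic with fixed durations; quiescent ->
premitotic activation, apoptosis and necrosis are stochastic.  A
stochastic transition with rate ``r`` fires in a step of length ``dt``
with probability ``r * dt`` (single uniform draw per cell per
transition, the discretization of an exponential waiting time at small
``r * dt``).

Component volumes relax toward phase-dependent targets,
``dV_i/dt = -r_{p,i} (V_i - V_i^p)``, integrated with an explicit Euler
step at the phase cadence.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .params import Phase, PhaseParams, VolumeParams
from .population import CellPopulation

__all__ = [
    "transition_probability",
    "proliferation_rate",
    "necrosis_rate",
    "update_phases",
    "update_volumes",
    "divide_cell",
    "apply_birth_death",
    "PhaseStepResult",
]

logger = logging.getLogger(__name__)


def transition_probability(rate: float, dt: float) -> float:
    """Probability that a transition with rate ``rate`` [1/hour] fires
    within ``dt`` minutes: ``rate * dt`` (in consistent units).

    Warns when ``rate * dt`` exceeds 1, where the linearization of the
    exponential waiting time is no longer a probability.
    """
    if np.any(np.asarray(rate) < 0):
        raise ValueError("transition rate must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = rate / 60.0 * dt
    if np.any(np.asarray(p) > 1.0):
        warnings.warn("rate * dt exceeds 1; decrease the phase time step")
    return p


def proliferation_rate(p_oxy, params: PhaseParams):
    """Oxygen-dependent quiescent -> premitotic activation rate [1/hour].

    Saturates at ``r_pro_max`` above ``Sa_pro``, ramps linearly on
    ``(Th_pro, Sa_pro)`` and vanishes at or below ``Th_pro``.
    """
    p = np.asarray(p_oxy, dtype=float)
    ramp = (p - params.Th_pro) / (params.Sa_pro - params.Th_pro)
    r = params.r_pro_max * np.clip(ramp, 0.0, 1.0)
    return r if r.ndim else float(r)


def necrosis_rate(p_oxy, params: PhaseParams):
    """Oxygen-dependent necrosis rate [1/hour].

    Zero at or above ``Th_nec``, ramps linearly as oxygen falls and
    saturates at ``r_nec_max`` at or below ``Sa_nec``.
    """
    p = np.asarray(p_oxy, dtype=float)
    ramp = (params.Th_nec - p) / (params.Th_nec - params.Sa_nec)
    r = params.r_nec_max * np.clip(ramp, 0.0, 1.0)
    return r if r.ndim else float(r)


@dataclass
class PhaseStepResult:
    """Bookkeeping of one phase step: division candidates and events."""

    division_indices: np.ndarray
    removal_flags: np.ndarray
    n_apoptotic_deaths: int = 0
    n_necrotic_deaths: int = 0
    n_activations: int = 0


def update_phases(pop: CellPopulation, p_oxy: np.ndarray, dt_phase: float,
                  pp: PhaseParams, vp: VolumeParams,
                  rng: np.random.Generator) -> PhaseStepResult:
    """Advance every cell's phase by one step of ``dt_phase`` minutes.

    Order within the step: (1) living cells test apoptosis, then
    necrosis, at the local oxygen level; (2) surviving premitotic cells
    whose clock has reached ``T_prem`` are queued for division; (3)
    postmitotic cells whose clock reached ``T_postm`` become quiescent;
    (4) quiescent cells test oxygen-dependent activation; (5) early
    necrotic cells that swelled past the rupture volume become late
    necrotic; (6) all clocks advance.  Dead cells shrunk below the
    removal threshold are flagged for deletion.
    """
    phase = pop.phase
    n = pop.n
    u_apop = rng.random(n)
    u_nec = rng.random(n)
    u_pro = rng.random(n)

    living = phase <= int(Phase.QUIESCENT)

    # (1) death tests: apoptosis first, then necrosis among survivors
    died_apop = living & (u_apop < transition_probability(pp.r_apop, dt_phase))
    p_nec = necrosis_rate(np.asarray(p_oxy, float), pp) / 60.0 * dt_phase
    died_nec = living & ~died_apop & (u_nec < p_nec)
    phase[died_apop] = int(Phase.APOPTOTIC)
    phase[died_nec] = int(Phase.EARLY_NECROTIC)
    died = died_apop | died_nec
    pop.phase_clock[died] = 0.0

    # (2) division candidates among surviving premitotic cells
    ready = (phase == int(Phase.PREMITOTIC)) & ~died & \
        (pop.phase_clock >= pp.T_prem * 60.0)
    division_indices = np.flatnonzero(ready)

    # (3) postmitotic -> quiescent after the fixed gap time
    done_postm = (phase == int(Phase.POSTMITOTIC)) & ~died & \
        (pop.phase_clock >= pp.T_postm * 60.0)
    phase[done_postm] = int(Phase.QUIESCENT)
    pop.phase_clock[done_postm] = 0.0

    # (4) quiescent activation at the oxygen-dependent rate
    p_pro = proliferation_rate(np.asarray(p_oxy, float), pp) / 60.0 * dt_phase
    activated = (phase == int(Phase.QUIESCENT)) & ~died & (u_pro < p_pro)
    phase[activated] = int(Phase.PREMITOTIC)
    pop.phase_clock[activated] = 0.0

    # (5) oncotic swelling past the rupture volume -> late necrosis
    ruptured = (phase == int(Phase.EARLY_NECROTIC)) & \
        (pop.V >= vp.rupture_ratio * vp.V_std)
    phase[ruptured] = int(Phase.LATE_NECROTIC)
    pop.phase_clock[ruptured] = 0.0

    # (6) clocks advance
    pop.phase_clock += dt_phase

    removal = (phase >= int(Phase.APOPTOTIC)) & \
        (pop.V < vp.removal_fraction * vp.V_std)
    pop.removal_flag = removal

    return PhaseStepResult(division_indices, removal,
                           int(died_apop.sum()), int(died_nec.sum()),
                           int(activated.sum()))


def update_volumes(pop: CellPopulation, dt_phase: float, vp: VolumeParams) -> None:
    """Explicit Euler step of the component volume relaxation ODEs, in place.

    Each component steps as ``V_i <- V_i - dt * r_{p,i} * (V_i - V_i^p)``.
    The fluid target is ``f_F * V`` for living phases, the current total
    volume for early necrotic cells (fluid uptake and swelling) and zero
    for apoptotic and late necrotic cells.  Total volume is recomputed
    as the component sum afterwards; negative components (possible only
    for unstable ``dt * r > 1``) are clamped to zero and logged.
    """
    ph = pop.phase
    dt_h = dt_phase / 60.0  # rates are per hour

    r_F = np.asarray(vp.r_F)[ph]
    r_NS = np.asarray(vp.r_NS)[ph]
    r_CS = np.asarray(vp.r_CS)[ph]
    t_NS = np.asarray(vp.V_NS_target)[ph]
    t_CS = np.asarray(vp.V_CS_target)[ph]

    living = ph <= int(Phase.QUIESCENT)
    early = ph == int(Phase.EARLY_NECROTIC)
    t_F = np.where(living, vp.f_F * pop.V, np.where(early, pop.V, 0.0))

    pop.V_F -= dt_h * r_F * (pop.V_F - t_F)
    pop.V_NS -= dt_h * r_NS * (pop.V_NS - t_NS)
    pop.V_CS -= dt_h * r_CS * (pop.V_CS - t_CS)

    for name in ("V_F", "V_NS", "V_CS"):
        arr = getattr(pop, name)
        neg = arr < 0.0
        if np.any(neg):
            logger.warning("%d negative %s values clamped to zero", neg.sum(), name)
            arr[neg] = 0.0

    pop.V = pop.V_F + pop.V_NS + pop.V_CS


def divide_cell(parent: int, pop: CellPopulation, rng: np.random.Generator):
    """Split cell ``parent`` into two daughters; return their states.

    Each daughter inherits half of every parent volume component and is
    placed at the parent center +- ``(R - R / 2^(1/3)) * theta`` with
    ``theta`` a uniformly random 3-D unit vector, so that two spheres of
    half volume straddle the parent center.  Daughters enter the
    postmitotic phase with a zeroed clock; velocities are copied from
    the parent.  Total volume is conserved exactly.
    """
    R = float(pop.radius[parent])
    theta = rng.normal(size=3)
    theta /= np.linalg.norm(theta)
    disp = (R - R / 2.0 ** (1.0 / 3.0)) * theta

    def daughter(sign):
        return {
            "position": pop.position[parent] + sign * disp,
            "velocity": pop.velocity[parent].copy(),
            "previous_velocity": pop.previous_velocity[parent].copy(),
            "phase": int(Phase.POSTMITOTIC),
            "phase_clock": 0.0,
            "V": pop.V[parent] / 2.0,
            "V_F": pop.V_F[parent] / 2.0,
            "V_NS": pop.V_NS[parent] / 2.0,
            "V_CS": pop.V_CS[parent] / 2.0,
        }

    return daughter(+1.0), daughter(-1.0)


def _assign(pop: CellPopulation, i: int, state: dict) -> None:
    pop.position[i] = state["position"]
    pop.velocity[i] = state["velocity"]
    pop.previous_velocity[i] = state["previous_velocity"]
    pop.phase[i] = state["phase"]
    pop.phase_clock[i] = state["phase_clock"]
    pop.V[i] = state["V"]
    pop.V_F[i] = state["V_F"]
    pop.V_NS[i] = state["V_NS"]
    pop.V_CS[i] = state["V_CS"]


def apply_birth_death(pop: CellPopulation, division_indices, removal_flags,
                      rng: np.random.Generator) -> CellPopulation:
    """Execute queued divisions and removals; return the compacted population.

    For each division the parent record is replaced in place by the
    first daughter and the second daughter is appended; removal-flagged
    records are then deleted.  No surviving record is altered.
    """
    division_indices = np.asarray(division_indices, dtype=np.int64)
    removal_flags = np.asarray(removal_flags, dtype=bool)

    appended = []
    for idx in division_indices:
        d1, d2 = divide_cell(int(idx), pop, rng)
        _assign(pop, int(idx), d1)
        appended.append(d2)

    keep = ~removal_flags
    new = CellPopulation(
        np.concatenate([pop.position[keep]] + [[d["position"]] for d in appended]),
        np.concatenate([pop.phase[keep]] + [[d["phase"]] for d in appended]),
        np.concatenate([pop.V[keep]] + [[d["V"]] for d in appended]),
        np.concatenate([pop.V_F[keep]] + [[d["V_F"]] for d in appended]),
        np.concatenate([pop.V_NS[keep]] + [[d["V_NS"]] for d in appended]),
        np.concatenate([pop.V_CS[keep]] + [[d["V_CS"]] for d in appended]),
        velocity=np.concatenate([pop.velocity[keep]] + [[d["velocity"]] for d in appended]),
        previous_velocity=np.concatenate(
            [pop.previous_velocity[keep]] + [[d["previous_velocity"]] for d in appended]),
        phase_clock=np.concatenate(
            [pop.phase_clock[keep]] + [[d["phase_clock"]] for d in appended]),
    )
    new.has_previous_velocity = pop.has_previous_velocity
    return new
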