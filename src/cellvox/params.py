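"""Model parameter sets, scenario configuration and their invariants.

All quantities are stored in the units they are usually quoted in
(hours for phase durations and rates, mmHg for oxygen partial pressure,
micrometers for lengths).  The simulation itself runs in minutes and
micrometers; hourly rates are converted where they are consumed.
"""
from __future__ import annotations

import enum
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Phase",
    "LIVING_PHASES",
    "DEAD_PHASES",
    "PhaseParams",
    "VolumeParams",
    "MechanicsParams",
    "MicroenvParams",
    "DuctGeometry",
    "SimulationConfig",
    "validate_config",
    "max_interaction_distance",
]


class Phase(enum.IntEnum):
    """Cell cycle / death phases.

    Three living phases (premitotic, postmitotic, quiescent) and three
    death phases.  Necrotic death is split into an early (oncosis,
    fluid uptake and swelling) and a late (post membrane rupture,
    fluid loss) stage.
    """

    PREMITOTIC = 0
    POSTMITOTIC = 1
    QUIESCENT = 2
    APOPTOTIC = 3
    EARLY_NECROTIC = 4
    LATE_NECROTIC = 5


LIVING_PHASES = (Phase.PREMITOTIC, Phase.POSTMITOTIC, Phase.QUIESCENT)
DEAD_PHASES = (Phase.APOPTOTIC, Phase.EARLY_NECROTIC, Phase.LATE_NECROTIC)

#: number of phases; per-phase parameter tuples have this length
N_PHASES = 6


@dataclass
class PhaseParams:
    """Phase-transition parameters (Ki67-advanced reference cell line).

    Attributes
    ----------
    T_prem, T_postm : float
        Deterministic durations of the premitotic / postmitotic phases [hour].
    r_apop : float
        Constant apoptosis rate of living cells [1/hour].
    r_pro_max, Sa_pro, Th_pro : float
        Maximum quiescent->premitotic activation rate [1/hour], oxygen level
        at which it saturates [mmHg] and oxygen level below which it is
        zero [mmHg].
    r_nec_max, Sa_nec, Th_nec : float
        Maximum necrosis rate [1/hour], oxygen level at which necrosis
        saturates [mmHg] and the necrosis onset threshold [mmHg].
    """

    T_prem: float = 13.0
    T_postm: float = 2.5
    r_apop: float = 0.0060
    r_pro_max: float = 0.1176
    Sa_pro: float = 10.0
    Th_pro: float = 5.0
    r_nec_max: float = 0.1667
    Sa_nec: float = 2.5
    Th_nec: float = 5.0


# Per-phase tuples are indexed by the ``Phase`` integer values:
# (PREMITOTIC, POSTMITOTIC, QUIESCENT, APOPTOTIC, EARLY_NECROTIC, LATE_NECROTIC)
@dataclass
class VolumeParams:
    """Component volume targets and relaxation rates (MCF-10A reference).

    Each cell is split into a fluid compartment ``V_F`` and solid biomass,
    the latter further split into nuclear ``V_NS`` and cytoplasmic ``V_CS``
    solids.  Every component relaxes toward a phase-dependent target at a
    phase-dependent rate.  The fluid target is ``f_F * V`` for living
    phases, the current total volume ``V`` for early necrotic cells
    (oncosis: the cell takes up fluid and swells) and zero for apoptotic
    and late necrotic cells.
    """

    f_F: float = 0.7502
    r_F: tuple = (3.0, 3.0, 3.0, 3.0, 0.67, 0.05)
    V_NS_target: tuple = (270.0, 135.0, 135.0, 0.0, 0.0, 0.0)
    r_NS: tuple = (0.33, 0.33, 0.33, 0.35, 0.013, 0.013)
    V_CS_target: tuple = (976.0, 488.0, 488.0, 0.0, 0.0, 0.0)
    r_CS: tuple = (0.27, 0.33, 0.33, 1.0, 0.0032, 0.0032)
    rupture_ratio: float = 2.0
    removal_fraction: float = 0.02

    def __post_init__(self):
        # guard against the easy-to-make mistake of swapping target/rate rows
        if len(self.r_F) != N_PHASES or len(self.V_NS_target) != N_PHASES:
            raise ValueError("per-phase tuples must have length %d" % N_PHASES)

    @property
    def V_std(self) -> float:
        """Standard (quiescent steady-state) total cell volume [um^3]."""
        solids = self.V_NS_target[Phase.QUIESCENT] + self.V_CS_target[Phase.QUIESCENT]
        return solids / (1.0 - self.f_F)

    @property
    def V_F_std(self) -> float:
        """Fluid volume of a standard quiescent cell [um^3]."""
        return self.f_F * self.V_std

    @property
    def R_std(self) -> float:
        """Radius of a standard quiescent cell [um]."""
        return (3.0 * self.V_std / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class MechanicsParams:
    """Center-based mechanics parameters.

    The drag coefficient ``eta`` is kept at 1 and the adhesion/repulsion
    strengths are expressed directly in um/min (drag absorbed into the
    force coefficients, as in the PhysiCell lineage of models).
    """

    C_cca: float = 0.4
    C_ccr: float = 10.0
    adhesion_distance_factor: float = 1.25
    eta: float = 1.0
    F_mot: tuple = (0.0, 0.0, 0.0)


@dataclass
class MicroenvParams:
    """Oxygen transport constants.

    ``U_o`` is the default per-cell oxygen consumption rate (10/min);
    the uptake of a voxel is the cell-volume-weighted sum of ``U_o`` over
    the living cells it contains.  Diffusion coefficient, decay rate and
    the Dirichlet boundary value follow the standard oxygen reference
    values of BioFVM-style microenvironment solvers.
    """

    U_o: float = 10.0          # 1/min
    D: float = 1.0e5           # um^2/min
    lam: float = 0.1           # 1/min
    boundary_value: float = 38.0  # mmHg
    rho_star: float = 38.0     # mmHg, saturation concentration


@dataclass
class DuctGeometry:
    """A rigid single-opening duct: a cylinder closed at one end.

    ``axis`` is the duct direction (unit vector), ``closed_end_position``
    the axial coordinate of the closed end along that axis and ``length``
    the lumen length from closed end to opening.
    """

    axis: tuple = (1.0, 0.0, 0.0)
    radius: float = 150.0
    length: float = 900.0
    closed_end_position: float = 0.0

    def axis_vector(self) -> np.ndarray:
        a = np.asarray(self.axis, dtype=float)
        return a / np.linalg.norm(a)


@dataclass
class SimulationConfig:
    """Full simulation configuration: time stepping, domain, parameters.

    Time steps are in minutes and must satisfy
    ``dt_diff <= dt_mech <= dt_phase`` with each larger step an integer
    multiple of the smaller (multiscale stepping: diffusion fastest,
    phase updates slowest).
    """

    scenario: str = "hds"            # "hds" | "dcis" | "custom"
    seed: int = 0

    # time stepping [min]
    dt_diff: float = 0.01
    dt_mech: float = 0.1
    dt_phase: float = 6.0
    t_end: float = 27000.0           # 450 h
    output_every: float = 360.0

    # oxygen is quasi-steady relative to cell motion; `diff_substeps`
    # limits the number of dt_diff solver steps taken per mechanics tick
    # (None = fully synchronous, dt_mech / dt_diff steps) and
    # `diff_burnin` equilibrates the field once at t = 0
    diff_substeps: Optional[int] = None
    diff_burnin: int = 0

    # domain (isotropic Cartesian voxel lattice, centered on the origin
    # unless an explicit origin is given)
    nx: int = 100
    ny: int = 100
    nz: int = 100
    dx: float = 25.0
    origin: Optional[tuple] = None

    # scenario geometry / seeding
    n_seed: int = 2347
    cluster_packing: float = 0.64    # random-close-packing volume fraction
    cluster_radius: Optional[float] = None
    duct: Optional[DuctGeometry] = None

    phase: PhaseParams = field(default_factory=PhaseParams)
    volume: VolumeParams = field(default_factory=VolumeParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    microenv: MicroenvParams = field(default_factory=MicroenvParams)

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        """Plain-data dict (tuples become lists, YAML/JSON friendly)."""
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            return x
        return plain(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key, typ in (
            ("phase", PhaseParams),
            ("volume", VolumeParams),
            ("mechanics", MechanicsParams),
            ("microenv", MicroenvParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**{k: _tupleize(v) for k, v in d[key].items()})
        if d.get("duct") is not None and isinstance(d["duct"], dict):
            d["duct"] = DuctGeometry(**{k: _tupleize(v) for k, v in d["duct"].items()})
        if d.get("origin") is not None:
            d["origin"] = tuple(d["origin"])
        return cls(**d)

    def copy(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    def domain_origin(self) -> np.ndarray:
        if self.origin is not None:
            return np.asarray(self.origin, dtype=float)
        half = 0.5 * self.dx * np.array([self.nx, self.ny, self.nz], float)
        return -half


def _tupleize(v):
    return tuple(v) if isinstance(v, list) else v


def max_interaction_distance(volume: VolumeParams, mechanics: MechanicsParams) -> float:
    """Maximum cell-cell interaction distance R_A for standard-size cells [um].

    The voxel side length must be at least this long for the 27-voxel
    neighborhood gather to see every interacting pair.
    """
    return mechanics.adhesion_distance_factor * 2.0 * volume.R_std


def _is_integer_multiple(big: float, small: float, rtol: float = 1e-9) -> bool:
    if small <= 0:
        return False
    ratio = big / small
    return abs(ratio - round(ratio)) <= rtol * max(1.0, abs(ratio)) and round(ratio) >= 1


def validate_config(config: SimulationConfig) -> list:
    """Check every parameter invariant; return a list of violation messages.

    An empty list means the configuration is valid.  Violations name the
    offending field and the rule; nothing is raised.
    """
    v: list = []
    c = config

    # time stepping
    for name in ("dt_diff", "dt_mech", "dt_phase"):
        if getattr(c, name) <= 0:
            v.append(f"{name}: must be positive")
    if c.dt_diff > 0 and c.dt_mech > 0 and c.dt_phase > 0:
        if not (c.dt_diff <= c.dt_mech <= c.dt_phase):
            v.append("dt_diff <= dt_mech <= dt_phase: ordering violated "
                     f"({c.dt_diff}, {c.dt_mech}, {c.dt_phase})")
        if not _is_integer_multiple(c.dt_mech, c.dt_diff):
            v.append(f"dt_mech ({c.dt_mech}) must be an integer multiple of dt_diff ({c.dt_diff})")
        if not _is_integer_multiple(c.dt_phase, c.dt_mech):
            v.append(f"dt_phase ({c.dt_phase}) must be an integer multiple of dt_mech ({c.dt_mech})")
    if c.t_end < 0:
        v.append("t_end: must be non-negative")
    if c.output_every <= 0:
        v.append("output_every: must be positive")
    if c.diff_substeps is not None and c.diff_substeps < 1:
        v.append("diff_substeps: must be >= 1 (or None for synchronous stepping)")
    if c.diff_burnin < 0:
        v.append("diff_burnin: must be non-negative")

    # phase params
    p = c.phase
    for name in ("T_prem", "T_postm", "r_apop", "r_pro_max", "Sa_pro", "Th_pro",
                 "r_nec_max", "Sa_nec", "Th_nec"):
        if getattr(p, name) < 0:
            v.append(f"phase.{name}: must be non-negative")
    if not p.Th_pro < p.Sa_pro:
        v.append(f"phase: Th_pro ({p.Th_pro}) must be < Sa_pro ({p.Sa_pro})")
    if not p.Sa_nec < p.Th_nec:
        v.append(f"phase: Sa_nec ({p.Sa_nec}) must be < Th_nec ({p.Th_nec})")

    # volume params
    w = c.volume
    if not (0.0 < w.f_F < 1.0):
        v.append(f"volume.f_F ({w.f_F}): must lie in (0, 1) for living phases")
    for name in ("r_F", "r_NS", "r_CS"):
        if any(r < 0 for r in getattr(w, name)):
            v.append(f"volume.{name}: rates must be non-negative")
    for name in ("V_NS_target", "V_CS_target"):
        if any(t < 0 for t in getattr(w, name)):
            v.append(f"volume.{name}: targets must be non-negative")
    if w.rupture_ratio <= 1.0:
        v.append(f"volume.rupture_ratio ({w.rupture_ratio}): must exceed 1")
    if not (0.0 < w.removal_fraction < 1.0):
        v.append(f"volume.removal_fraction ({w.removal_fraction}): must lie in (0, 1)")

    # mechanics
    m = c.mechanics
    if m.C_cca < 0 or m.C_ccr < 0:
        v.append("mechanics: C_cca and C_ccr must be non-negative")
    if m.adhesion_distance_factor < 1.0:
        v.append(f"mechanics.adhesion_distance_factor ({m.adhesion_distance_factor}): must be >= 1")
    if m.eta <= 0:
        v.append("mechanics.eta: must be positive")

    # microenvironment
    u = c.microenv
    for name in ("U_o", "D", "boundary_value", "rho_star"):
        if getattr(u, name) <= 0:
            v.append(f"microenv.{name}: must be positive")
    if u.lam < 0:
        v.append("microenv.lam: must be non-negative")

    # grid
    if c.dx <= 0 or min(c.nx, c.ny, c.nz) < 1:
        v.append("grid: dx must be positive and voxel counts >= 1")
    elif 0.0 < w.f_F < 1.0:  # R_std is ill-defined otherwise
        r_a = max_interaction_distance(w, m)
        if c.dx < r_a:
            v.append(f"grid.dx ({c.dx} um): must be >= the maximum cell-cell "
                     f"interaction distance R_A ({r_a:.2f} um)")

    # duct
    if c.duct is not None:
        if c.duct.radius <= 0:
            v.append("duct.radius: must be positive")
        else:
            half_cross = 0.5 * c.dx * min(c.ny, c.nz)
            if c.duct.radius + c.dx > half_cross:
                v.append(f"duct.radius ({c.duct.radius} um): duct plus wall shell must "
                         f"fit inside the domain cross-section ({half_cross} um half-width)")

    if c.n_seed < 0:
        v.append("n_seed: must be non-negative")
    if not (0.0 < c.cluster_packing <= 0.74):
        v.append(f"cluster_packing ({c.cluster_packing}): must lie in (0, 0.74]")
    if c.scenario not in ("hds", "dcis", "custom"):
        v.append(f"scenario ({c.scenario!r}): must be 'hds', 'dcis' or 'custom'")
    if c.scenario == "dcis" and c.duct is None:
        v.append("scenario 'dcis' requires a duct geometry")

    return v
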