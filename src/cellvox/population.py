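"""Structure-of-arrays container for the discrete cell population."""
from __future__ import annotations

import numpy as np

from .params import Phase

__all__ = ["CellPopulation"]

_VOLUME_RTOL = 1e-6


class CellPopulation:
    """All per-cell state stored as parallel numpy arrays.

    Arrays (all length ``n``, positions/velocities ``(n, 3)``):

    - ``position`` [um], ``velocity`` and ``previous_velocity`` [um/min]
    - ``phase`` (int8, :class:`~cellvox.params.Phase` values) and
      ``phase_clock`` (time spent in the current phase [min])
    - component volumes ``V``, ``V_F``, ``V_NS``, ``V_CS`` [um^3] with
      ``V == V_F + V_NS + V_CS``
    - ``sort_key`` (Morton code of the containing voxel, set by
      :func:`cellvox.mechanics.sort_by_voxel`) and ``removal_flag``

    ``has_previous_velocity`` is False until the first mechanics step has
    produced a velocity; the position integrator then falls back to a
    forward-Euler bootstrap step.
    """

    def __init__(self, position, phase, V, V_F, V_NS, V_CS,
                 velocity=None, previous_velocity=None, phase_clock=None):
        self.position = np.ascontiguousarray(position, dtype=np.float64).reshape(-1, 3)
        n = self.position.shape[0]
        self.phase = np.asarray(phase, dtype=np.int8).reshape(n)
        self.V = np.asarray(V, dtype=np.float64).reshape(n).copy()
        self.V_F = np.asarray(V_F, dtype=np.float64).reshape(n).copy()
        self.V_NS = np.asarray(V_NS, dtype=np.float64).reshape(n).copy()
        self.V_CS = np.asarray(V_CS, dtype=np.float64).reshape(n).copy()
        self.velocity = (np.zeros((n, 3)) if velocity is None
                         else np.asarray(velocity, float).reshape(n, 3).copy())
        self.previous_velocity = (np.zeros((n, 3)) if previous_velocity is None
                                  else np.asarray(previous_velocity, float).reshape(n, 3).copy())
        self.phase_clock = (np.zeros(n) if phase_clock is None
                            else np.asarray(phase_clock, float).reshape(n).copy())
        self.sort_key = np.zeros(n, dtype=np.uint64)
        self.removal_flag = np.zeros(n, dtype=bool)
        self.has_previous_velocity = False

    # ------------------------------------------------------------------
    @classmethod
    def empty(cls) -> "CellPopulation":
        z = np.zeros((0, 3))
        return cls(z, np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0))

    @property
    def n(self) -> int:
        return self.position.shape[0]

    @property
    def radius(self) -> np.ndarray:
        """Cell radii derived from total volume: R = (3V / 4 pi)^(1/3) [um]."""
        return (3.0 * self.V / (4.0 * np.pi)) ** (1.0 / 3.0)

    @property
    def living(self) -> np.ndarray:
        return self.phase <= int(Phase.QUIESCENT)

    # ------------------------------------------------------------------
    def permute(self, order: np.ndarray) -> None:
        """Reorder all per-cell arrays in place by ``order``."""
        for name in ("position", "velocity", "previous_velocity", "phase",
                     "phase_clock", "V", "V_F", "V_NS", "V_CS", "sort_key",
                     "removal_flag"):
            setattr(self, name, np.ascontiguousarray(getattr(self, name)[order]))

    def copy(self) -> "CellPopulation":
        out = CellPopulation(self.position.copy(), self.phase.copy(), self.V,
                             self.V_F, self.V_NS, self.V_CS,
                             velocity=self.velocity, previous_velocity=self.previous_velocity,
                             phase_clock=self.phase_clock)
        out.sort_key = self.sort_key.copy()
        out.removal_flag = self.removal_flag.copy()
        out.has_previous_velocity = self.has_previous_velocity
        return out

    def validate(self, rtol: float = _VOLUME_RTOL) -> None:
        """Raise ``ValueError`` if any state invariant is violated."""
        comp = self.V_F + self.V_NS + self.V_CS
        bad = ~np.isclose(self.V, comp, rtol=rtol, atol=1e-9)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"cell {i}: V ({self.V[i]}) != V_F+V_NS+V_CS ({comp[i]}) beyond rtol={rtol}")
        for name in ("V", "V_F", "V_NS", "V_CS"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name}: negative volumes present")
        if np.any((self.phase < 0) | (self.phase > int(Phase.LATE_NECROTIC))):
            raise ValueError("phase: labels outside the six-phase enumeration")

    def phase_counts(self) -> np.ndarray:
        """Number of cells in each of the six phases."""
        return np.bincount(self.phase, minlength=6)
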