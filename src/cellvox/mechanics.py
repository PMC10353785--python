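"""Center-based cell mechanics with voxel-sorted neighbor search.

Cells are elastic spheres interacting through short-range adhesion and
repulsion.  Forces are aggregated in linear time: each cell receives a
Morton (Z-order) key from its voxel index, the cell arrays are sorted by
key so cells sharing a voxel become contiguous, and each cell then sums
pairwise forces over the cells of its 27-voxel neighborhood only.  This
is valid whenever the voxel side length is at least the maximum
cell-cell interaction distance (validated at grid construction).

In the overdamped (inertialess) limit the velocity equals the total
force divided by the drag coefficient; positions advance with the
second-order Adams-Bashforth rule.
"""
from __future__ import annotations

import logging

import numba
import numpy as np

from .grid import Grid
from .params import DuctGeometry, MechanicsParams
from .population import CellPopulation

__all__ = [
    "morton_encode",
    "morton_decode",
    "sort_by_voxel",
    "pairwise_force",
    "aggregate_forces",
    "velocities",
    "update_positions",
    "apply_confinement",
]

logger = logging.getLogger(__name__)

_U64 = np.uint64


def _part1by2(x: np.ndarray) -> np.ndarray:
    """Spread the low 21 bits of each element, leaving two zero bits between."""
    x = x.astype(np.uint64) & _U64(0x1FFFFF)
    x = (x | (x << _U64(32))) & _U64(0x1F00000000FFFF)
    x = (x | (x << _U64(16))) & _U64(0x1F0000FF0000FF)
    x = (x | (x << _U64(8))) & _U64(0x100F00F00F00F00F)
    x = (x | (x << _U64(4))) & _U64(0x10C30C30C30C30C3)
    x = (x | (x << _U64(2))) & _U64(0x1249249249249249)
    return x


def morton_encode(i, j, k, shape=None) -> np.ndarray:
    """Morton (Z-order) key of voxel indices.

    Bit ``b`` of ``i`` lands at key bit ``3b``, of ``j`` at ``3b + 1``
    and of ``k`` at ``3b + 2``.  Indices must be non-negative, fit in 21
    bits, and (if ``shape`` is given) lie inside the grid.
    """
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    k = np.asarray(k, dtype=np.int64)
    if np.any(i < 0) or np.any(j < 0) or np.any(k < 0):
        raise ValueError("voxel indices must be non-negative")
    if max(i.max(initial=0), j.max(initial=0), k.max(initial=0)) >= (1 << 21):
        raise ValueError("voxel indices must fit in 21 bits")
    if shape is not None:
        nx, ny, nz = shape
        if np.any(i >= nx) or np.any(j >= ny) or np.any(k >= nz):
            raise ValueError("voxel index outside the grid")
    key = _part1by2(i) | (_part1by2(j) << _U64(1)) | (_part1by2(k) << _U64(2))
    return key


def morton_decode(key) -> tuple:
    """Inverse of :func:`morton_encode`."""
    key = np.asarray(key, dtype=np.uint64)

    def compact(x):
        x = x & _U64(0x1249249249249249)
        x = (x | (x >> _U64(2))) & _U64(0x10C30C30C30C30C3)
        x = (x | (x >> _U64(4))) & _U64(0x100F00F00F00F00F)
        x = (x | (x >> _U64(8))) & _U64(0x1F0000FF0000FF)
        x = (x | (x >> _U64(16))) & _U64(0x1F00000000FFFF)
        x = (x | (x >> _U64(32))) & _U64(0x1FFFFF)
        return x.astype(np.int64)

    return compact(key), compact(key >> _U64(1)), compact(key >> _U64(2))


# ----------------------------------------------------------------------
def sort_by_voxel(pop: CellPopulation, grid: Grid) -> np.ndarray:
    """Sort the cell arrays by ascending Morton key (stable), in place.

    Fills ``grid.voxel_start`` / ``grid.voxel_end`` with the contiguous
    index range of each voxel's cells in the sorted arrays (empty voxels
    have ``start == end == 0``).  Returns the permutation applied.
    """
    ivox = grid.voxel_index(pop.position)
    keys = morton_encode(ivox[:, 0], ivox[:, 1], ivox[:, 2])
    order = np.argsort(keys, kind="stable")
    pop.permute(order)
    pop.sort_key = keys[order]

    grid.voxel_start[:] = 0
    grid.voxel_end[:] = 0
    if pop.n:
        lin = grid.linear_index(ivox[order])
        cut = np.flatnonzero(lin[1:] != lin[:-1]) + 1
        starts = np.concatenate(([0], cut))
        ends = np.concatenate((cut, [pop.n]))
        grid.voxel_start[lin[starts]] = starts
        grid.voxel_end[lin[starts]] = ends
    return order


# ----------------------------------------------------------------------
def pairwise_force(xi, xj, Ri: float, Rj: float, params: MechanicsParams) -> np.ndarray:
    """Adhesion + repulsion force exerted on cell i by cell j [um/min].

    With ``r = xj - xi``, ``R_R = Ri + Rj`` and
    ``R_A = adhesion_distance_factor * R_R``:

    - adhesion  ``+C_cca * (1 - |r|/R_A)^2 * r_hat``  for ``|r| <= R_A``
    - repulsion ``-C_ccr * (1 - |r|/R_R)^2 * r_hat``  for ``|r| <= R_R``

    and zero beyond ``R_A``.  Antisymmetric under i <-> j.  Coincident
    centers (|r| = 0) fall back to a repulsion of magnitude ``C_ccr``
    along -x (the voxel-sorted aggregator disambiguates the sign with
    the cell ordering so that the pair still satisfies Newton's third
    law); the event is logged.
    """
    r = np.asarray(xj, float) - np.asarray(xi, float)
    d = float(np.linalg.norm(r))
    RR = Ri + Rj
    RA = params.adhesion_distance_factor * RR
    if d == 0.0:
        logger.warning("coincident cell centers; applying fallback repulsion")
        return np.array([-params.C_ccr, 0.0, 0.0])
    f = np.zeros(3)
    if d <= RA:
        f += params.C_cca * (1.0 - d / RA) ** 2 * r / d
    if d <= RR:
        f -= params.C_ccr * (1.0 - d / RR) ** 2 * r / d
    return f


@numba.njit(cache=True)
def _aggregate_kernel(pos, rad, ivox, vstart, vend, nx, ny, nz,
                      C_cca, C_ccr, adh_factor, fmot):  # pragma: no cover
    n = pos.shape[0]
    out = np.empty((n, 3))
    for a in range(n):
        fx, fy, fz = fmot[0], fmot[1], fmot[2]
        ia, ja, ka = ivox[a, 0], ivox[a, 1], ivox[a, 2]
        for di in range(-1, 2):
            i = ia + di
            if i < 0 or i >= nx:
                continue
            for dj in range(-1, 2):
                j = ja + dj
                if j < 0 or j >= ny:
                    continue
                for dk in range(-1, 2):
                    k = ka + dk
                    if k < 0 or k >= nz:
                        continue
                    v = i + nx * (j + ny * k)
                    for b in range(vstart[v], vend[v]):
                        if b == a:
                            continue
                        rx = pos[b, 0] - pos[a, 0]
                        ry = pos[b, 1] - pos[a, 1]
                        rz = pos[b, 2] - pos[a, 2]
                        RR = rad[a] + rad[b]
                        RA = adh_factor * RR
                        d2 = rx * rx + ry * ry + rz * rz
                        if d2 > RA * RA:
                            continue
                        d = np.sqrt(d2)
                        if d == 0.0:
                            # coincident centers: deterministic fallback along x
                            s = -1.0 if a < b else 1.0
                            fx += s * C_ccr
                            continue
                        m = C_cca * (1.0 - d / RA) ** 2
                        if d <= RR:
                            m -= C_ccr * (1.0 - d / RR) ** 2
                        fx += m * rx / d
                        fy += m * ry / d
                        fz += m * rz / d
        out[a, 0] = fx
        out[a, 1] = fy
        out[a, 2] = fz
    return out


def aggregate_forces(pop: CellPopulation, grid: Grid, params: MechanicsParams) -> np.ndarray:
    """Total force on every cell via the 27-voxel neighborhood gather.

    Requires :func:`sort_by_voxel` to have been applied this mechanics
    step so that ``grid.voxel_start``/``voxel_end`` index the sorted
    arrays.  Includes the (default zero) locomotive force ``F_mot``.
    """
    ivox = grid.voxel_index(pop.position)
    fmot = np.asarray(params.F_mot, dtype=float)
    return _aggregate_kernel(
        pop.position, pop.radius, ivox, grid.voxel_start, grid.voxel_end,
        grid.nx, grid.ny, grid.nz,
        float(params.C_cca), float(params.C_ccr),
        float(params.adhesion_distance_factor), fmot)


def velocities(forces: np.ndarray, params: MechanicsParams) -> np.ndarray:
    """Overdamped velocities: v = F_total / eta [um/min]."""
    return forces / params.eta


def update_positions(pop: CellPopulation, v_now: np.ndarray, dt_mech: float) -> None:
    """Second-order Adams-Bashforth position update, in place.

    ``x <- x + dt/2 * (3 v_now - v_prev)``.  On the very first mechanics
    step no previous velocity exists and the update falls back to
    forward Euler (equivalent to taking ``v_prev = v_now``).
    """
    if not pop.has_previous_velocity:
        pop.previous_velocity = v_now.copy()
        pop.has_previous_velocity = True
    pop.position += 0.5 * dt_mech * (3.0 * v_now - pop.previous_velocity)
    pop.previous_velocity = v_now.copy()
    pop.velocity = v_now


def apply_confinement(pop: CellPopulation, grid: Grid,
                      duct: DuctGeometry = None) -> None:
    """Project escaped cells back into the allowed region, in place.

    Every cell center is clamped into the domain box (with a margin of
    one cell radius).  With a duct, centers are additionally confined to
    the lumen: radial distance at most ``R_duct - R_cell`` and axial
    coordinate at least one cell radius past the closed end.  Previous
    velocities are left untouched.
    """
    R = pop.radius
    lo = grid.origin[None, :] + R[:, None]
    hi = grid.upper[None, :] - R[:, None]
    np.clip(pop.position, lo, hi, out=pop.position)

    if duct is not None:
        a = duct.axis_vector()
        rel = pop.position - duct.closed_end_position * a[None, :]
        axial = rel @ a
        radial_vec = rel - axial[:, None] * a[None, :]
        radial = np.linalg.norm(radial_vec, axis=1)
        r_max = duct.radius - R
        over = radial > r_max
        if np.any(over):
            scale = np.ones_like(radial)
            nz = radial > 0
            scale[over & nz] = (r_max / radial)[over & nz]
            radial_vec *= scale[:, None]
        axial = np.maximum(axial, R)
        pop.position[:] = (duct.closed_end_position * a[None, :]
                           + axial[:, None] * a[None, :] + radial_vec)
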