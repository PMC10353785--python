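"""Finite-volume oxygen transport in the extracellular fluid.

The substrate obeys

    d rho / dt = div(D grad rho) - lam * rho + S * (rho* - rho) - U * rho

and is advanced with first-order operator splitting: a locally
one-dimensional (LOD) implicit diffusion-decay solve (three sequential
tridiagonal sweeps, one per axis, each carrying a third of the decay),
followed by an implicit supply/uptake update.  Every tridiagonal system
is solved with the Thomas algorithm in O(n).

Dirichlet boundaries are realized as pinned voxel sets whose values are
re-imposed after every sweep; the natural boundary closure of the
finite-volume rows is zero-flux (Neumann).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numba
import numpy as np

from .grid import Grid
from .population import CellPopulation
from .params import MicroenvParams

__all__ = [
    "Field",
    "compute_uptake",
    "supply_uptake_step",
    "build_tridiagonal",
    "thomas_solve",
    "lod_diffusion_step",
    "sample_concentration",
]


@dataclass
class Field:
    """Per-voxel concentration of one diffusible substance.

    Attributes
    ----------
    rho : ndarray, shape (nx, ny, nz)
        Concentration [mmHg for oxygen].
    rho_star : float
        Saturation concentration toward which supply pushes.
    D, lam : float
        Diffusion coefficient [um^2/min] and decay rate [1/min].
    S, U : float or ndarray
        Supply and uptake rate per voxel [1/min].
    dirichlet_mask, dirichlet_values : ndarray, optional
        Voxels pinned to fixed values after every operator application
        (domain faces, duct-wall shells, ...).
    """

    rho: np.ndarray
    rho_star: float
    D: float
    lam: float
    S: Union[float, np.ndarray] = 0.0
    U: Union[float, np.ndarray] = 0.0
    dirichlet_mask: Optional[np.ndarray] = None
    dirichlet_values: Union[float, np.ndarray] = 0.0

    def __post_init__(self):
        self._pin_flat = None
        self._pin_vals = None

    def refresh_pins(self) -> None:
        """Rebuild the cached pinned-voxel index after mutating the mask."""
        self._pin_flat = None
        self._pin_vals = None

    def pin(self) -> None:
        """Re-impose pinned (Dirichlet) voxel values exactly."""
        if self.dirichlet_mask is None:
            return
        if self._pin_flat is None:
            self._pin_flat = np.flatnonzero(self.dirichlet_mask.ravel())
            if np.isscalar(self.dirichlet_values):
                self._pin_vals = np.full(self._pin_flat.size,
                                         float(self.dirichlet_values))
            else:
                self._pin_vals = self.dirichlet_values.ravel()[self._pin_flat].copy()
        self.rho.ravel()[self._pin_flat] = self._pin_vals

    def copy(self) -> "Field":
        return Field(self.rho.copy(), self.rho_star, self.D, self.lam,
                     self.S if np.isscalar(self.S) else self.S.copy(),
                     self.U if np.isscalar(self.U) else self.U.copy(),
                     None if self.dirichlet_mask is None else self.dirichlet_mask.copy(),
                     self.dirichlet_values if np.isscalar(self.dirichlet_values)
                     else self.dirichlet_values.copy())


# ----------------------------------------------------------------------
def compute_uptake(pop: CellPopulation, grid: Grid, uparams: MicroenvParams) -> np.ndarray:
    """Per-voxel total oxygen uptake rate map [1/min].

    Each living cell contributes ``(V_cell / V_voxel) * U_o`` to the
    uptake rate of its containing voxel; dead cells consume nothing.
    """
    U = np.zeros(grid.n_voxels)
    living = pop.living
    if np.any(living):
        lin = grid.linear_index(grid.voxel_index(pop.position[living]))
        np.add.at(U, lin, pop.V[living])
        U *= uparams.U_o / grid.voxel_volume
    return np.ascontiguousarray(U.reshape(grid.shape, order="F"))


@numba.njit(cache=True)
def _supply_uptake_kernel(rho, U, S, rho_star, dt):  # pragma: no cover
    src = dt * S * rho_star
    for i in range(rho.size):
        rho[i] = (rho[i] + src) / (1.0 + dt * (S + U[i]))


def supply_uptake_step(field: Field, dt_diff: float) -> None:
    """Implicit first-order supply/uptake update, in place.

    rho <- (rho + dt * S * rho*) / (1 + dt * (S + U)); pinned voxels are
    re-imposed afterwards.  Unconditionally stable and non-negativity
    preserving for non-negative inputs.
    """
    if np.isscalar(field.S) and isinstance(field.U, np.ndarray) \
            and field.rho.flags.c_contiguous and field.U.flags.c_contiguous:
        _supply_uptake_kernel(field.rho.ravel(), field.U.ravel(),
                              float(field.S), float(field.rho_star), dt_diff)
    else:
        field.rho = (field.rho + dt_diff * field.S * field.rho_star) / \
            (1.0 + dt_diff * (field.S + field.U))
    field.pin()


# ----------------------------------------------------------------------
def build_tridiagonal(n: int, D: float, lam: float, dt: float, dx: float):
    """Coefficient arrays of one implicit LOD sweep along an axis of length n.

    Interior rows carry ``1 + dt*lam/3 + 2*dt*D/dx^2`` on the diagonal and
    ``-dt*D/dx^2`` off-diagonal; the first and last rows lose one flux
    term (zero-flux closure).  Returns ``(sub, diag, sup)`` with ``sub``
    and ``sup`` of length ``n - 1``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    alpha = dt * D / dx ** 2
    base = 1.0 + dt * lam / 3.0
    diag = np.full(n, base + 2.0 * alpha)
    if n == 1:
        return np.zeros(0), np.array([base]), np.zeros(0)
    diag[0] = base + alpha
    diag[-1] = base + alpha
    sub = np.full(n - 1, -alpha)
    sup = np.full(n - 1, -alpha)
    return sub, diag, sup


def thomas_solve(sub, diag, sup, rhs) -> np.ndarray:
    """Solve a single tridiagonal system in O(n) (Thomas algorithm).

    ``sub``/``sup`` are the sub- and super-diagonals (length n-1),
    ``diag`` the diagonal (length n).  Requires non-vanishing pivots,
    which diagonal dominance guarantees.
    """
    sub = np.asarray(sub, float)
    diag = np.asarray(diag, float)
    sup = np.asarray(sup, float)
    rhs = np.asarray(rhs, float)
    n = diag.size
    cp = np.empty(max(n - 1, 0))
    g = np.empty(n)
    w = diag[0]
    if w == 0.0:
        raise ZeroDivisionError("zero pivot in Thomas algorithm at row 0")
    g[0] = rhs[0] / w
    for i in range(1, n):
        cp[i - 1] = sup[i - 1] / w
        w = diag[i] - sub[i - 1] * cp[i - 1]
        if w == 0.0:
            raise ZeroDivisionError(f"zero pivot in Thomas algorithm at row {i}")
        g[i] = (rhs[i] - sub[i - 1] * g[i - 1]) / w
    x = np.empty(n)
    x[-1] = g[-1]
    for i in range(n - 2, -1, -1):
        x[i] = g[i] - cp[i] * x[i + 1]
    return x


def _thomas_factor(sub, diag, sup):
    """Precompute elimination coefficients shared by all strips of a sweep."""
    n = diag.size
    cp = np.empty(max(n - 1, 0))
    w = np.empty(n)
    w[0] = diag[0]
    for i in range(1, n):
        cp[i - 1] = sup[i - 1] / w[i - 1]
        w[i] = diag[i] - sub[i - 1] * cp[i - 1]
    if np.any(w == 0.0):
        raise ZeroDivisionError("zero pivot in Thomas factorization")
    return cp, w


def _thomas_solve_batch(sub, cp, w, rhs2d) -> np.ndarray:
    """Thomas back/forward substitution for many right-hand sides.

    ``rhs2d`` has shape (n, m): one tridiagonal system per column, all
    sharing the same coefficient arrays.
    """
    n, m = rhs2d.shape
    g = np.empty_like(rhs2d)
    g[0] = rhs2d[0] / w[0]
    for i in range(1, n):
        g[i] = (rhs2d[i] - sub[i - 1] * g[i - 1]) / w[i]
    x = g
    for i in range(n - 2, -1, -1):
        x[i] -= cp[i] * x[i + 1]
    return x


@numba.njit(cache=True)
def _sweep_axis0(rho, a, w, cp):  # pragma: no cover
    nx = rho.shape[0]
    m = rho.shape[1] * rho.shape[2]
    r = rho.reshape(nx, m)
    for j in range(m):
        r[0, j] /= w[0]
    for i in range(1, nx):
        wi = w[i]
        for j in range(m):
            r[i, j] = (r[i, j] - a * r[i - 1, j]) / wi
    for i in range(nx - 2, -1, -1):
        ci = cp[i]
        for j in range(m):
            r[i, j] -= ci * r[i + 1, j]


@numba.njit(cache=True)
def _sweep_axis1(rho, a, w, cp):  # pragma: no cover
    nx, ny, nz = rho.shape
    for i in range(nx):
        for k in range(nz):
            rho[i, 0, k] /= w[0]
        for j in range(1, ny):
            wj = w[j]
            for k in range(nz):
                rho[i, j, k] = (rho[i, j, k] - a * rho[i, j - 1, k]) / wj
        for j in range(ny - 2, -1, -1):
            cj = cp[j]
            for k in range(nz):
                rho[i, j, k] -= cj * rho[i, j + 1, k]


@numba.njit(cache=True)
def _sweep_axis2(rho, a, w, cp):  # pragma: no cover
    # four independent strips are interleaved per inner iteration so the
    # serial k-recurrences overlap (instruction-level parallelism)
    nx, ny, nz = rho.shape
    for i in range(nx):
        j0 = 0
        while j0 + 4 <= ny:
            for jj in range(j0, j0 + 4):
                rho[i, jj, 0] /= w[0]
            for k in range(1, nz):
                wk = w[k]
                rho[i, j0, k] = (rho[i, j0, k] - a * rho[i, j0, k - 1]) / wk
                rho[i, j0 + 1, k] = (rho[i, j0 + 1, k] - a * rho[i, j0 + 1, k - 1]) / wk
                rho[i, j0 + 2, k] = (rho[i, j0 + 2, k] - a * rho[i, j0 + 2, k - 1]) / wk
                rho[i, j0 + 3, k] = (rho[i, j0 + 3, k] - a * rho[i, j0 + 3, k - 1]) / wk
            for k in range(nz - 2, -1, -1):
                ck = cp[k]
                rho[i, j0, k] -= ck * rho[i, j0, k + 1]
                rho[i, j0 + 1, k] -= ck * rho[i, j0 + 1, k + 1]
                rho[i, j0 + 2, k] -= ck * rho[i, j0 + 2, k + 1]
                rho[i, j0 + 3, k] -= ck * rho[i, j0 + 3, k + 1]
            j0 += 4
        for j in range(j0, ny):
            rho[i, j, 0] /= w[0]
            for k in range(1, nz):
                rho[i, j, k] = (rho[i, j, k] - a * rho[i, j, k - 1]) / w[k]
            for k in range(nz - 2, -1, -1):
                rho[i, j, k] -= cp[k] * rho[i, j, k + 1]


_SWEEPS = (_sweep_axis0, _sweep_axis1, _sweep_axis2)


def lod_diffusion_step(field: Field, grid: Grid, dt_diff: float,
                       axis_order=(0, 1, 2)) -> None:
    """One implicit LOD diffusion-decay step, in place.

    Performs three sequential one-dimensional sweeps (x, then y, then z
    by default), each solving one tridiagonal system per perpendicular
    strip with a third of the decay rate.  Pinned voxels are re-imposed
    after every sweep.
    """
    field.pin()
    rho = field.rho
    if not rho.flags.c_contiguous:
        rho = np.ascontiguousarray(rho)
        field.rho = rho
    alpha = dt_diff * field.D / grid.dx ** 2
    for axis in axis_order:
        n = grid.shape[axis]
        sub, diag, sup = build_tridiagonal(n, field.D, field.lam, dt_diff, grid.dx)
        if n == 1:
            rho /= diag[0]
        else:
            cp, w = _thomas_factor(sub, diag, sup)
            _SWEEPS[axis](rho, -alpha, w, cp)
        field.pin()


def sample_concentration(pop: CellPopulation, field: Field, grid: Grid) -> np.ndarray:
    """Per-cell oxygen partial pressure: the value of the containing voxel.

    Nearest-voxel lookup (no interpolation), matching the resolution at
    which uptake is deposited.
    """
    idx = grid.voxel_index(pop.position)
    return field.rho[idx[:, 0], idx[:, 1], idx[:, 2]]
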