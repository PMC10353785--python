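"""Isotropic Cartesian voxel lattice shared by mechanics and diffusion."""
from __future__ import annotations

import numpy as np

__all__ = ["Grid"]


class Grid:
    """Isotropic voxel grid.

    Parameters
    ----------
    nx, ny, nz : int
        Voxel counts along each axis.
    dx : float
        Voxel side length [um]; a single value for all three axes.
    origin : array-like of length 3, optional
        Coordinates of the lower corner of voxel (0, 0, 0).  Defaults to
        centering the domain on the coordinate origin.
    min_interaction_distance : float, optional
        If given, construction fails unless ``dx`` is at least this long;
        used to guarantee that the 27-voxel neighbor gather sees every
        mechanically interacting cell pair.

    After :func:`cellvox.mechanics.sort_by_voxel` the attributes
    ``voxel_start``/``voxel_end`` hold, for every voxel (linear index),
    the contiguous index range of its cells in the sorted cell arrays.
    """

    def __init__(self, nx, ny, nz, dx, origin=None, min_interaction_distance=None):
        if min(nx, ny, nz) < 1 or dx <= 0:
            raise ValueError("grid needs positive voxel counts and dx")
        if min_interaction_distance is not None and dx < min_interaction_distance:
            raise ValueError(
                f"dx ({dx} um) must be >= the maximum cell-cell interaction "
                f"distance ({min_interaction_distance:.2f} um)")
        self.nx, self.ny, self.nz = int(nx), int(ny), int(nz)
        self.dx = float(dx)
        if origin is None:
            origin = -0.5 * self.dx * np.array([nx, ny, nz], dtype=float)
        self.origin = np.asarray(origin, dtype=float).reshape(3)
        self.voxel_start = np.zeros(self.n_voxels, dtype=np.int64)
        self.voxel_end = np.zeros(self.n_voxels, dtype=np.int64)

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return (self.nx, self.ny, self.nz)

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def voxel_volume(self) -> float:
        return self.dx ** 3

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.dx * np.array(self.shape, dtype=float)

    # ------------------------------------------------------------------
    def voxel_index(self, position) -> np.ndarray:
        """(i, j, k) index of the voxel containing each position.

        Uses the ``floor((x - origin) / dx)`` convention: a point an
        epsilon inside a voxel face belongs to that voxel, not to its
        neighbor.  Indices are clipped into the domain so that positions
        sitting exactly on the upper boundary map to the last voxel.
        """
        pos = np.asarray(position, dtype=float).reshape(-1, 3)
        idx = np.floor((pos - self.origin) / self.dx).astype(np.int64)
        np.clip(idx, 0, np.array(self.shape) - 1, out=idx)
        return idx

    def linear_index(self, ivox) -> np.ndarray:
        iv = np.asarray(ivox, dtype=np.int64).reshape(-1, 3)
        return iv[:, 0] + self.nx * (iv[:, 1] + self.ny * iv[:, 2])

    def contains(self, position) -> np.ndarray:
        pos = np.asarray(position, dtype=float).reshape(-1, 3)
        return np.all((pos >= self.origin) & (pos <= self.upper), axis=1)

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + self.dx * (np.arange(n) + 0.5)

    def center_voxel(self) -> tuple:
        return (self.nx // 2, self.ny // 2, self.nz // 2)
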