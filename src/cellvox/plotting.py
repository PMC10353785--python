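"""Quick-look plots for inspection (not publication rendering)."""
from __future__ import annotations

import numpy as np

from .params import Phase
from .population import CellPopulation

PHASE_COLORS = {
    Phase.PREMITOTIC: "tab:green",
    Phase.POSTMITOTIC: "tab:olive",
    Phase.QUIESCENT: "tab:blue",
    Phase.APOPTOTIC: "tab:purple",
    Phase.EARLY_NECROTIC: "tab:orange",
    Phase.LATE_NECROTIC: "tab:brown",
}


def central_slice(pop: CellPopulation, axis: int = 2, thickness: float = 60.0,
                  field=None, grid=None, ax=None):
    """Scatter the cells of a central slab, optionally over the oxygen field.

    Returns the matplotlib axes.  ``thickness`` is the slab width [um]
    centered on the population centroid along ``axis``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    other = [a for a in range(3) if a != axis]
    center = pop.position[:, axis].mean() if pop.n else 0.0
    sel = np.abs(pop.position[:, axis] - center) <= 0.5 * thickness

    if field is not None and grid is not None:
        k = int(np.clip((center - grid.origin[axis]) / grid.dx, 0,
                        grid.shape[axis] - 1))
        sl = [slice(None)] * 3
        sl[axis] = k
        img = field.rho[tuple(sl)]
        extent = [grid.origin[other[0]], grid.upper[other[0]],
                  grid.origin[other[1]], grid.upper[other[1]]]
        ax.imshow(img.T, origin="lower", extent=extent, cmap="Greys_r", alpha=0.6)

    for phase in Phase:
        m = sel & (pop.phase == int(phase))
        if np.any(m):
            ax.scatter(pop.position[m, other[0]], pop.position[m, other[1]],
                       s=4, color=PHASE_COLORS[phase], label=phase.name.lower())
    ax.set_aspect("equal")
    ax.set_xlabel("um")
    ax.set_ylabel("um")
    ax.legend(loc="upper right", fontsize=7)
    return ax
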