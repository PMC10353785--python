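"""Scalar observables: spheroid radii, phase counts, DCIS front and rate.

The discrete population has no sharp surface, so "radius" is estimated
as a high percentile (default 97.5) of cell-center distances from the
population centroid plus the mean cell radius; this is robust to a few
straggler cells while still tracking the outer shell.
"""
from __future__ import annotations

import numpy as np

from .params import DuctGeometry, Phase
from .population import CellPopulation

__all__ = [
    "spheroid_radius",
    "necrotic_core_radius",
    "duct_front",
    "dcis_front_and_rate",
]

MINUTES_PER_DAY = 1440.0


def _radius_estimate(position, cell_radius, percentile, use_max):
    centroid = position.mean(axis=0)
    dist = np.linalg.norm(position - centroid, axis=1)
    core = dist.max() if use_max else np.percentile(dist, percentile)
    return float(core + cell_radius.mean())


def spheroid_radius(pop: CellPopulation, percentile: float = 97.5,
                    use_max: bool = False) -> float:
    """Spheroid radius estimate [um] over all cells.

    ``percentile`` of center distances from the centroid plus the mean
    cell radius; ``use_max=True`` switches to the maximum distance.
    Raises on an empty population.
    """
    if pop.n == 0:
        raise ValueError("spheroid radius is undefined for an empty population")
    return _radius_estimate(pop.position, pop.radius, percentile, use_max)


def necrotic_core_radius(pop: CellPopulation, percentile: float = 97.5,
                         use_max: bool = False) -> float:
    """Same estimator restricted to (early + late) necrotic cells; 0 if none."""
    nec = (pop.phase == int(Phase.EARLY_NECROTIC)) | \
        (pop.phase == int(Phase.LATE_NECROTIC))
    if not np.any(nec):
        return 0.0
    return _radius_estimate(pop.position[nec], pop.radius[nec], percentile, use_max)


def duct_front(pop: CellPopulation, duct: DuctGeometry,
               percentile: float = 99.0) -> float:
    """Axial position of the advancing tumor front [um].

    The ``percentile`` of the axial coordinates (along the duct axis) of
    living cells; NaN if no living cells remain.
    """
    living = pop.living
    if not np.any(living):
        return float("nan")
    axial = pop.position[living] @ duct.axis_vector()
    return float(np.percentile(axial, percentile))


def dcis_front_and_rate(times_min, populations, duct: DuctGeometry,
                        percentile: float = 99.0):
    """Front positions over a snapshot series and the advance rate.

    Returns ``(fronts, rate)`` where ``fronts`` [um] has one entry per
    snapshot and ``rate`` [um/day] is the least-squares slope of front
    position versus time.  Needs at least two snapshots.
    """
    times_min = np.asarray(times_min, dtype=float)
    if times_min.size < 2:
        raise ValueError("need at least two snapshots to fit an advance rate")
    fronts = np.array([duct_front(p, duct, percentile) for p in populations])
    slope_per_min = np.polyfit(times_min, fronts, 1)[0]
    return fronts, float(slope_per_min * MINUTES_PER_DAY)
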