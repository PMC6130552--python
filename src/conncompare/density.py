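"""Proportional density thresholding and density-window / AUC machinery.

Comparing connectomes at a single threshold confounds topology with edge
count, so metrics are traced across an ordered grid of network densities
(fractions of possible edges retained) and summarized as areas under the
metric-vs-density curve (AUC), both over the full analysis range and in
windows split where the group mean curves cross.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .io import Connectome, DensityWindow, MetricCurve, ValidationError

logger = logging.getLogger("conncompare")


@dataclass
class ThresholdedNetwork:
    """A connectome thresholded to a target density."""

    matrix: np.ndarray
    target_density: float
    binary: bool
    parent: Connectome | None = None

    @property
    def density(self) -> float:
        n = self.matrix.shape[0]
        iu = np.triu_indices(n, k=1)
        return np.count_nonzero(self.matrix[iu]) / (n * (n - 1) / 2)


def _ranked_edges(matrix: np.ndarray):
    """Upper-triangle edges sorted by weight descending, ties by (i, j).

    Lexicographic tie-breaking makes proportional thresholding deterministic
    across runs and platforms.
    """
    n = matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = matrix[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def threshold_at_density(
    conn: Connectome, d: float, binarize: bool = False
) -> ThresholdedNetwork:
    """Retain the floor(d * N(N-1)/2) strongest edges of a weighted connectome."""
    n = conn.n_nodes
    m_total = n * (n - 1) // 2
    if not (0 < d <= 1):
        raise ValidationError(f"density must lie in (0, 1], got {d}")
    m_keep = int(np.floor(d * m_total + 1e-9))
    if m_keep < 1:
        raise ValidationError(f"density {d} keeps no edges (grid too fine for N={n})")
    iu, ju, w = _ranked_edges(conn.matrix)
    present = w > 0
    iu, ju, w = iu[present], ju[present], w[present]
    m_keep = min(m_keep, w.size)
    out = np.zeros_like(conn.matrix)
    vals = np.ones(m_keep) if binarize else w[:m_keep]
    out[iu[:m_keep], ju[:m_keep]] = vals
    out[ju[:m_keep], iu[:m_keep]] = vals
    return ThresholdedNetwork(out, d, binarize, conn)


def is_connected(matrix: np.ndarray) -> bool:
    n_comp, _ = connected_components(matrix != 0, directed=False)
    return n_comp == 1


def minimum_connection_density(
    connectomes: list[Connectome], grid: np.ndarray
) -> float:
    """Smallest grid density at which every subject's network is connected.

    Scans the grid in increasing order; a subject whose network stays
    disconnected even with all its edges present is an error.
    """
    if not connectomes:
        raise ValidationError("need at least one connectome")
    ns = {c.n_nodes for c in connectomes}
    if len(ns) != 1:
        raise ValidationError(f"mixed node counts {ns}")
    bad = [c.subject_id or f"#{i}" for i, c in enumerate(connectomes)
           if not is_connected(c.matrix)]
    if bad:
        raise ValidationError(
            f"subject(s) disconnected even at full density: {bad}"
        )
    n = connectomes[0].n_nodes
    m_total = n * (n - 1) // 2
    for d in np.asarray(grid, dtype=float):
        if int(np.floor(d * m_total + 1e-9)) < 1:
            continue  # grid point too fine to keep any edge
        if all(is_connected(threshold_at_density(c, float(d)).matrix)
               for c in connectomes):
            return float(d)
    raise ValidationError("no grid density connects every subject")


def small_world_density_range(
    sigma_curves: list[MetricCurve],
    d_min: float,
    d_max: float = 0.5,
    rule: str = "mean",
) -> DensityWindow:
    """Density window from d_min to the last small-world density (<= d_max).

    Small-worldness requires sigma > 1 (strict). ``rule="mean"`` applies the
    criterion to the group-mean curve; ``rule="all"`` requires every subject
    to exceed 1.
    """
    grid = sigma_curves[0].grid
    for c in sigma_curves[1:]:
        if not np.array_equal(c.grid, grid):
            raise ValidationError("sigma curves must share a common grid")
    stacked = np.vstack([c.values for c in sigma_curves])
    crit = stacked.mean(axis=0) if rule == "mean" else stacked.min(axis=0)
    eligible = (grid >= d_min - 1e-12) & (grid <= d_max + 1e-12) & (crit > 1)
    if not eligible.any():
        raise ValidationError("no small-world regime: sigma never exceeds 1")
    start = np.searchsorted(grid, d_min - 1e-12)
    last = start
    for i in range(start, grid.size):
        if grid[i] > d_max + 1e-12 or crit[i] <= 1:
            break
        last = i
    if last == start:
        raise ValidationError("small-world regime does not extend past d_min")
    return DensityWindow(float(grid[start]), float(grid[last]))


def find_crossover(
    mean_a: MetricCurve, mean_b: MetricCurve
) -> float | None:
    """First grid density where the sign of (A - B) changes, else None.

    Used to split the analysis range into two AUC windows at the density
    where the group mean curves cross.
    """
    if not np.array_equal(mean_a.grid, mean_b.grid):
        raise ValidationError("curves must share a common grid")
    diff = mean_a.values - mean_b.values
    sign = np.sign(diff)
    prev = 0.0
    for i, s in enumerate(sign):
        if s == 0:
            continue
        if prev != 0 and s != prev:
            return float(mean_a.grid[i])
        prev = s
    return None


def auc_over_window(curve: MetricCurve, window: DensityWindow) -> float:
    """Trapezoidal integral of the metric over density within the window."""
    grid = curve.grid
    lo = np.nonzero(np.isclose(grid, window.d_lo))[0]
    hi = np.nonzero(np.isclose(grid, window.d_hi))[0]
    if lo.size == 0 or hi.size == 0:
        raise ValidationError(
            f"window [{window.d_lo}, {window.d_hi}] endpoints not on the grid"
        )
    sl = slice(lo[0], hi[0] + 1)
    return float(np.trapezoid(curve.values[sl], grid[sl]))


def group_mean_curve(curves: list[MetricCurve], name: str = "mean") -> MetricCurve:
    grid = curves[0].grid
    vals = np.vstack([c.values for c in curves]).mean(axis=0)
    return MetricCurve(name, grid, vals)
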