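"""The 2D ecometric trait-space grid.

Trait space is the plane spanned by two community summaries (by default the
community mean and SD of the trait). It is partitioned into an equally spaced
grid; the number of bins per axis defaults to Scott's rule. Intervals are
half-open [e_i, e_{i+1}) except the last, which is closed so the maximum
training value is binned. Bin indices are 0-based.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def optimal_bins(x) -> int:
    """Number of histogram bins for ``x`` under Scott's rule.

    Scott's rule picks the bin width h = 3.49 * s * n**(-1/3), with s the
    sample standard deviation (n-1 denominator) and n the sample size; the
    bin count is ceil(range / h), at least 1. The count is invariant under
    positive rescaling of the data, since range and s scale together.

    Raises
    ------
    ValueError if fewer than two values or the sample SD is zero.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("optimal_bins requires at least 2 finite values")
    s = float(np.std(x, ddof=1))
    if s == 0.0:
        raise ValueError("cannot bin constant data (zero variance)")
    h = 3.49 * s * n ** (-1.0 / 3.0)
    return max(1, math.ceil((x.max() - x.min()) / h))


@dataclass
class TraitGrid:
    """Equally spaced 2D grid over (metric1, metric2) trait space.

    ``edges1``/``edges2`` have length B+1 and span [min, max] of the training
    metrics on each axis. ``membership`` maps each valid training point_id to
    its (i, j) bin.
    """

    edges1: np.ndarray
    edges2: np.ndarray
    membership: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def b1(self) -> int:
        return len(self.edges1) - 1

    @property
    def b2(self) -> int:
        return len(self.edges2) - 1

    def __eq__(self, other):
        return (
            isinstance(other, TraitGrid)
            and np.array_equal(self.edges1, other.edges1)
            and np.array_equal(self.edges2, other.edges2)
            and self.membership == other.membership
        )


def _assign_axis(edges: np.ndarray, x: float, clamp: bool) -> tuple[int, bool]:
    """Locate ``x`` on one axis; returns (index, out_of_range)."""
    nbins = len(edges) - 1
    if x < edges[0]:
        if not clamp:
            raise ValueError(f"value {x} below grid minimum {edges[0]}")
        return 0, True
    if x > edges[-1]:
        if not clamp:
            raise ValueError(f"value {x} above grid maximum {edges[-1]}")
        return nbins - 1, True
    if x == edges[-1]:  # last interval is closed on the right
        return nbins - 1, False
    idx = int(np.searchsorted(edges, x, side="right")) - 1
    return min(max(idx, 0), nbins - 1), False


def assign_bin(grid: TraitGrid, metric1: float, metric2: float, clamp: bool = False):
    """Assign a (metric1, metric2) pair to a grid bin.

    Returns ``(i, j, out_of_range)``. Values outside the grid raise unless
    ``clamp`` is set, in which case they land in the nearest edge bin with
    ``out_of_range=True`` — used when projecting fossil communities whose
    summaries fall outside the modern trait space.
    """
    if not (np.isfinite(metric1) and np.isfinite(metric2)):
        raise ValueError(f"non-finite metrics ({metric1}, {metric2})")
    i, oor1 = _assign_axis(grid.edges1, float(metric1), clamp)
    j, oor2 = _assign_axis(grid.edges2, float(metric2), clamp)
    return i, j, (oor1 or oor2)


def _axis_edges(values: np.ndarray, nbins: int, axis_name: str) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError(
            f"cannot grid {axis_name}: all values equal {lo} (no spread to bin)"
        )
    return np.linspace(lo, hi, nbins + 1)


def make_grid(
    summaries: pd.DataFrame, bins1: int | None = None, bins2: int | None = None
) -> TraitGrid:
    """Construct the trait grid from valid community summaries.

    Only rows flagged ``valid`` with both metrics present enter the grid.
    Bin counts default to Scott's rule on each metric. Every such training
    point is assigned a bin, recorded in ``membership``.
    """
    use = summaries[
        summaries["valid"]
        & summaries["metric1"].notna()
        & summaries["metric2"].notna()
    ]
    if len(use) < 2:
        raise ValueError("need at least 2 valid summaries with both metrics to build a grid")
    m1 = use["metric1"].to_numpy(dtype=float)
    m2 = use["metric2"].to_numpy(dtype=float)
    if bins1 is None:
        bins1 = optimal_bins(m1)
    if bins2 is None:
        bins2 = optimal_bins(m2)
    grid = TraitGrid(
        edges1=_axis_edges(m1, int(bins1), "metric1"),
        edges2=_axis_edges(m2, int(bins2), "metric2"),
    )
    for pid, a, b in zip(use["point_id"].astype(str), m1, m2):
        i, j, _ = assign_bin(grid, a, b)
        grid.membership[pid] = (i, j)
    occupied = len(set(grid.membership.values()))
    if occupied == 1:
        logger.warning("all %d training points fall in a single grid bin", len(use))
    return grid
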